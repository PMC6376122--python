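# erpfield

Mass-univariate ERP statistics, global electric-field analyses and
distributed source localization for high-density EEG studies of contextual
face perception — with a synthetic data generator that emulates a
three-condition (Neutral / Fear / Happiness) film-editing paradigm, so the
entire pipeline is testable end to end without any recordings.

## Who this is for

EEG/ERP researchers who contrast paired experimental conditions with:

1. **Point-wise paired t-maps** over electrodes × time, pruned by a temporal
   persistence criterion (≥ 10 contiguous samples, i.e. 20 ms at 500 Hz) and
   a spatial extent criterion (≥ 5 adjacent electrodes within one of nine
   scalp clusters), with a paired **sign-flip randomization test** for
   multiple-comparison control;
2. **Reference-free global field statistics**: Global Field Power
   `GFP(t) = sd_channels(V(t))` for field *strength*, and global
   dissimilarity
   `DISS(a, b) = sqrt(mean_i (a_i/GFP(a) − b_i/GFP(b))²)  ∈ [0, 2]`
   for field *topography* (`DISS² = 2(1 − r)` with `r` the spatial
   correlation), each tested with label-exchange randomization — the
   randomization test on DISS being the **TANOVA**;
3. **LAURA-regularized distributed source localization** on a three-shell
   spherical head model: local autoregressive operator `A` with
   inverse-squared-distance weights on the 26-neighborhood, source metric
   `M = (AᵀA)⁻¹`, inverse operator `G = M Lᵀ (L M Lᵀ + λ²I)⁻¹`, and
   voxel-wise paired t-tests on RMS-normalized current densities with a
   contiguity threshold (clusters ≥ 10 solution points; smaller ones are
   reported sub-threshold).

The synthetic module generates the balanced 288-trial design (96 trials per
condition, 24 face identities × 12 repetitions, identity–context pairing
unique, gender/orientation balanced), multichannel epochs built from P1 /
N170 / N2 / LPP component templates with condition-dependent amplitudes and
latencies plus spatially and temporally correlated noise, and trial-level
valence/arousal ratings with configurable context effects.

## Worked example

```bash
python examples/02_mass_univariate_stats.py
```

generates a reduced synthetic study (12 participants × 60 trials per
condition on the 110-channel montage) and prints the surviving
Fear-vs-Neutral effects:

```
comparison: Fear vs Neutral; 2 surviving effect(s)

    180-  190 ms  peak t= +6.08 around E58 (PL) randomization=ok
    492-  548 ms  peak t= +6.72 around E80 (CM) randomization=ok
```

Each line is one spatio-temporal effect that lasted ≥ 20 ms over ≥ 5
adjacent same-cluster electrodes at p < 0.01 and survived the sign-flip
randomization: the posterior N170-window effect (weaker negativity when the
context was fearful) and the late-positive-potential (LPP) enhancement for
the emotional context; the full study size (19 × 80) also resolves the early
P1 latency difference.  The
other examples cover the montage and design (`01`), the GFP/TANOVA
strength-vs-topography dissociation (`03`), single-dipole recovery by the
LAURA inverse (`04`), and the behavioral ratings (`05`).

A thin CLI wraps the same library calls:

```bash
erpfield simulate --out scratch/sim --seed 1
erpfield run-all  --out scratch/report --seed 1
```

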