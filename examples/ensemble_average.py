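"""Reweighted ensemble averaging of scores over boosted-MD frames.

Boosted molecular dynamics (e.g. Gaussian-accelerated MD) adds a boost energy
DeltaV that must be reweighted out.  Frame weights follow the second-order
cumulant expansion, log w = beta<DeltaV> + beta^2 var(DeltaV)/2.  Here two
conformations of a dipeptide get different boost statistics; the hydrophobicity
score is then averaged with those weights.
"""

import numpy as np

import hydroscore as hs

frame_a = hs.make_ideal_peptide("GW", seed=1).structure
frame_b = hs.make_ideal_peptide("GW", seed=2).structure  # different conformer
rng = np.random.default_rng(0)
ens = hs.FrameEnsemble(
    frames=[frame_a, frame_b],
    boost_energies=[rng.normal(2.0, 0.3, size=50), rng.normal(2.6, 0.3, size=50)],
    temperature=300.0,
)
w = hs.ensemble_weights(ens)
print(f"frame weights: {w[0]:.3f}, {w[1]:.3f} "
      "(the frame with higher boost energy dominates)")

scale = hs.load_scale("wimley-white")


def pos_surf(frame):
    sasa = hs.shrake_rupley(frame, n_points=240)
    return hs.pos_surf_score(frame, sasa, hs.assign_hydrophobicity(frame, scale))


avg = hs.ensemble_score(ens, pos_surf)
print(f"per-frame scores: {pos_surf(frame_a):.1f}, {pos_surf(frame_b):.1f}")
print(f"reweighted ensemble score: {avg:.1f} (hydrophobicity x A^2)")
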