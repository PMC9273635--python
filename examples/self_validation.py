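"""Self-validation with half-phased and unphased contacts.

Real single-cell Hi-C contacts carry allele labels only where SNVs happen
to cover both legs; here a 30% per-leg phasing mask mimics that.  Only the
phased contacts (~9%) drive the reconstruction; the ambiguous majority then
tests it: a half-phased contact is satisfied if the best of its 2 candidate
allele assignments is within the detection limit, an unphased contact if
the best of its 4 is.  No allele label is ever imputed.
"""

import rp3d
from rp3d.contacts_io import PhasingClass, classify_phasing

truth = rp3d.simulate_polymer(n_chroms=1, beads_per_chain=500,
                              two_alleles=True, seed=21)
threshold = rp3d.threshold_for_recurrence_rate(truth, 0.075)
exp = rp3d.derive_contacts(truth, threshold, q_detect=1.0, phasing_rate=0.3,
                           seed=21)

counts = {pc: 0 for pc in PhasingClass}
for c in exp.contacts:
    counts[classify_phasing(c)] += 1
print("contact composition:",
      {pc.value: n for pc, n in counts.items()})

phased = [c for c in exp.contacts
          if classify_phasing(c) is PhasingClass.PHASED]
emb = rp3d.reconstruct_cell(phased, resolution=truth.resolution)
print(f"reconstructed from {len(phased)} phased contacts "
      f"({len(emb.segments)} segments)")

report = rp3d.consistency_ratios(emb, exp.contacts)
print(report.to_frame().to_string(index=False))
print(f"(fraction of contacts satisfied within the detection limit "
      f"{report.detection_limit:.4f}; the held-out half-phased/unphased "
      f"classes scoring close to the phased class — which the embedding "
      f"was fitted to — validates the phased-only reconstruction without "
      f"ever assigning the ambiguous alleles)")
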