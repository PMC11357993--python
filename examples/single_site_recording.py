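"""Multiplex single-site recording: three signal recorders write distinct
barcodes to one shared tape locus; editing scores normalise each barcode's
genomic abundance by its plasmid-pool abundance, so the score tracks
recorder activity rather than construct dosage."""

from engram import (
    SimConfig,
    default_hek3_channels,
    design_vocabulary,
    editing_fraction,
    editing_score,
    hill_rate,
    simulate_hek3_sample,
)

channels = default_hek3_channels()
vocab = design_vocabulary(k=5, n=3, min_dist=3, seed=7)
vocab = type(vocab)(k=5, entries=dict(zip(("TET", "NFKB", "WNT"),
                                          vocab.entries.values())))

# a 48-hour exposure: doxycycline high, TNF moderate, CHIR absent
doses = {"TET": 2.0, "NFKB": 2.5, "WNT": 0.0}
activities = {ch.symbol_id: hill_rate(doses[ch.name], ch) for ch in channels}
plasmid_props = {s: 1 / 3 for s in activities}

genomic, plasmid = simulate_hek3_sample(
    activities, vocab, plasmid_props,
    SimConfig(n_cells=5000, tapes_per_cell=20, seed=1), duration_days=2.0)

print(f"edited fraction of tape copies: {editing_fraction(genomic):.4f}")
for sym in activities:
    score = editing_score(genomic, plasmid, sym)
    print(f"  {sym:5s} rate {activities[sym]:.5f}/day  "
          f"counts {genomic.counts[sym]:6d}  editing score {score:.2f}")
print("Scores above 1 mean the barcode is over-represented among edits "
      "relative to its plasmid abundance: the corresponding pathway was on.")
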