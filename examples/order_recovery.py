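"""Temporal-order recording on a five-unit sequential tape: simulate the
twelve serial/layered two-agonist programmes, sequence and decode the tape,
and infer which agonist came first from the sign of the adjacent-site
bigram log2-ratio."""

from engram import ReadModel, SimConfig, TapeSpec, default_tape_channels, order_recovery_experiment

df = order_recovery_experiment(
    channels=default_tape_channels(),
    spec=TapeSpec(),
    config=SimConfig(n_cells=500, tapes_per_cell=20),  # desk scale
    seeds=[1, 2, 3],
    read_model=ReadModel(reads_per_sample=5000, per_base_error=0.001),
)

summary = (df.groupby(["programme", "pattern", "first_channel"])
             ["bigram_log_ratio"].mean().reset_index())
print(summary.to_string(index=False, float_format=lambda v: f"{v:+.2f}"))
n_ok = df.groupby("programme")["sign_correct"].first().sum()
print(f"\nsign-correct programmes: {int(n_ok)}/12")
print("Positive ratios mean (first -> second) bigrams dominate, so the "
      "listed first_channel was indeed applied first; serial programmes "
      "give larger ratios than layered ones, and longer first exposures "
      "give larger ratios still.")
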