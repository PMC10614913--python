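"""Simulate a 15N pulse-chase experiment and inspect the ground truth.

Draws a 40-protein proteome whose turnover rates come from a two-component
mixture (fast majority, long-lived tail), then prints the true fractional
abundance — the percent of each pool still 15N-labeled — after 6 and 10
months of 14N chase. Long-lived proteins retain tens of percent; typical
proteins are effectively fully exchanged.
"""

from isopulse import ProteomeConfig, simulate_proteome

config = ProteomeConfig(n_proteins=40, llp_fraction=0.15)
sequences, truth = simulate_proteome(config, seed=1)

table = truth.table.sort_values("fa_6", ascending=False)
print(f"{'protein':10s} {'half-life (mo)':>14s} {'FA 6 mo (%)':>12s} {'FA 10 mo (%)':>13s}  LLP")
for row in table.head(10).itertuples():
    print(
        f"{row.protein_id:10s} {row.half_life_months:14.2f} {getattr(row, 'fa_6'):12.2f} "
        f"{getattr(row, 'fa_10'):13.2f}  {'yes' if row.is_llp else 'no'}"
    )
n_llp = int(truth.table["is_llp"].sum())
print(
    f"\n{n_llp}/{len(table)} proteins drawn from the long-lived component; "
    "their FA stays high through the chase while the rest decay to ~0%."
)
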