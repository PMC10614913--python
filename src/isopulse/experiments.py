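"""End-to-end synthetic experiments exercising the whole pipeline.

Each function generates ground-truthed synthetic data, runs the relevant
pipeline stage(s) from scratch and returns the recovery metrics. They back
the worked examples and the reproducibility script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .isotope_chem import peptide_composition
from .llp_pipeline import (
    FilterConfig,
    call_llps,
    calls_to_frame,
    filter_peptides,
    fractional_abundance,
)
from .mims_imaging import nuc_cyto_ratio, ratio_image, roi_stats, RoiSet
from .quant_ms import (
    QuantConfig,
    estimate_enrichment,
    quantify_run,
    records_to_frame,
)
from .synthetic_data import (
    Ms1Params,
    ProteomeConfig,
    RegionSpec,
    cell_field_layout,
    select_peptides,
    simulate_proteome,
    synthesize_mims_fields,
    synthesize_ms1_run,
)


def fa_recovery_experiment(
    n_peptides: int = 100,
    noise: bool = True,
    seed: int = 3,
    proteome: ProteomeConfig | None = None,
) -> pd.DataFrame:
    """Generate a run, quantify it, and tabulate recovered vs true FA.

    Returns the merged per-peptide table with columns ``true_fa`` and
    ``recovered_fa`` (NaN where quantification failed).
    """
    cfg = proteome or ProteomeConfig(n_proteins=max(25, n_peptides // 4))
    sequences, truth = simulate_proteome(cfg, seed=seed)
    peptides = select_peptides(sequences, per_protein=4)[:n_peptides]
    params = Ms1Params() if noise else Ms1Params.noiseless()
    synth = synthesize_ms1_run(peptides, truth, params, seed=seed)
    records = quantify_run(synth.run, synth.identifications(), QuantConfig())
    df = records_to_frame(records).merge(
        synth.peptides, left_on=["peptide", "protein"], right_on=["peptide", "protein"]
    )
    rec_fa = np.full(len(df), np.nan)
    ok = df["valid"].to_numpy()
    rec_fa[ok] = fractional_abundance(df.loc[ok, "ar"].to_numpy())
    df["recovered_fa"] = rec_fa
    # the pipeline only consumes ratios that survive the correlation filter;
    # it is what removes co-elution interference from an overlapping window
    df["passes_correlation"] = df["is_singleton"] | (df["r"] > 0.5)
    return df


def fa_rmse(table: pd.DataFrame) -> float:
    """RMSE of recovered vs true FA in percentage points.

    Computed over valid records that survive the correlation gate — the same
    population whose FA the pipeline reports.
    """
    sub = table.dropna(subset=["recovered_fa"])
    if "passes_correlation" in sub.columns:
        sub = sub[sub["passes_correlation"]]
    err = sub["recovered_fa"].to_numpy() - sub["true_fa"].to_numpy()
    return float(np.sqrt(np.mean(err**2)))


def llp_benchmark(
    n_proteins: int = 200,
    llp_fraction: float = 0.15,
    seed: int = 5,
    mode: str = "tissue",
    filter_config: FilterConfig | None = None,
) -> dict:
    """LLP-calling operating characteristics against generator ground truth.

    Returns precision, recall and the underlying call table merged with the
    truth flags.
    """
    cfg = ProteomeConfig(n_proteins=n_proteins, llp_fraction=llp_fraction)
    sequences, truth = simulate_proteome(cfg, seed=seed)
    peptides = select_peptides(sequences, per_protein=5)
    synth = synthesize_ms1_run(peptides, truth, Ms1Params(), seed=seed)
    records = quantify_run(synth.run, synth.identifications(), QuantConfig())
    fc = filter_config or FilterConfig()
    passing, _ = filter_peptides(records, fc)
    calls = call_llps(passing, mode=mode, config=fc, all_records=records)
    call_df = calls_to_frame(calls)
    merged = truth.table.merge(
        call_df[["protein", "is_llp"]].rename(columns={"is_llp": "called_llp"}),
        left_on="protein_id",
        right_on="protein",
        how="left",
    )
    merged["called_llp"] = merged["called_llp"].astype("boolean").fillna(False).astype(bool)
    tp = int((merged["is_llp"] & merged["called_llp"]).sum())
    fp = int((~merged["is_llp"] & merged["called_llp"]).sum())
    fn = int((merged["is_llp"] & ~merged["called_llp"]).sum())
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    return {
        "precision": precision,
        "recall": recall,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "table": merged,
        "records": records,
        "calls": calls,
    }


def ape_roundtrip(
    enrichments=(0.2, 0.5, 0.8, 0.95),
    sequence: str = "LNDAGFIKEQTVR",
    noise_counts: float | None = None,
    seed: int = 11,
) -> pd.DataFrame:
    """Envelope round-trip: generate at e, re-estimate APE from intensities.

    With ``noise_counts`` set, the theoretical envelope is sampled as a
    multinomial with that many total ion counts (Poisson-like shot noise).
    """
    from .isotope_chem import isotope_envelope

    comp = peptide_composition(sequence)
    rng = np.random.default_rng(seed)
    rows = []
    for e in enrichments:
        env = isotope_envelope(comp, e)
        intensities = env.probabilities.copy()
        if noise_counts is not None:
            counts = rng.multinomial(int(noise_counts), intensities / intensities.sum())
            intensities = counts.astype(float)
        ape, sim = estimate_enrichment(intensities, comp, env.neutron_shifts)
        rows.append({"true_e": e, "ape": ape, "similarity": sim,
                     "abs_error": abs(ape - e)})
    return pd.DataFrame(rows)


def mims_recovery_experiment(
    percents=(0.0, 50.0, 150.0, 300.0),
    dose: float = 10_000.0,
    region_pixels: int = 3600,
    seed: int = 9,
) -> pd.DataFrame:
    """Region percent-above recovery on a synthetic field.

    Each region is a square of ``region_pixels`` pixels at the given percent
    above background. Returns the ROI table with generating values and the
    z-score of the deviation (in units of the ROI standard error).
    """
    side = int(np.sqrt(region_pixels))
    pad = 6
    shape = (side + 2 * pad, len(percents) * (side + pad) + pad)
    regions = []
    for i, p in enumerate(percents):
        c0 = pad + i * (side + pad)
        regions.append(
            RegionSpec(i + 1, p, ("rect", pad, c0, pad + side, c0 + side),
                       class_tag=f"P{p:g}")
        )
    stack = synthesize_mims_fields(shape, regions, mean_14n_counts=dose, seed=seed)
    img = ratio_image(stack)
    rois = RoiSet(stack.labels, {i + 1: f"P{p:g}" for i, p in enumerate(percents)})
    table = roi_stats(img, rois)
    table["true_percent_above"] = list(percents)
    table["z"] = (
        table["mean_percent_above"] - table["true_percent_above"]
    ) / table["se_percent_above"]
    return table


def nuc_cyto_experiment(
    n_cells: int = 20,
    dose: float = 10_000.0,
    nucleus_multiplier: float = 2.0,
    seed: int = 9,
):
    """Recover a generated nuclear enrichment from synthetic cell fields.

    Cells have cytoplasm at 100% above background and nuclei at
    ``nucleus_multiplier`` times the cytoplasmic ratio. Returns the per-cell
    table and the one-sample t-test of the ratio-of-means against 1.
    """
    shape = (200, 200)
    specs = cell_field_layout(n_cells, shape, nucleus_ratio_multiplier=nucleus_multiplier)
    stack = synthesize_mims_fields(shape, specs, mean_14n_counts=dose, seed=seed)
    img = ratio_image(stack)
    nucleus_labels = np.where(stack.labels > 1000, stack.labels - 1000, 0)
    cell_labels = np.where(
        (stack.labels > 0) & (stack.labels <= 1000), stack.labels, 0
    )
    cell_labels = np.where(nucleus_labels > 0, nucleus_labels, cell_labels)
    return nuc_cyto_ratio(img, nucleus_labels, cell_labels)


def type_one_error_rates(
    n_sims: int = 2000, n: int = 30, alpha: float = 0.05, seed: int = 13
) -> dict[str, float]:
    """Null rejection rates of the package's tests over simulated data."""
    from .stats_report import (
        kw_with_posthoc,
        one_sample_test,
        one_way_anova,
        two_group_test,
    )

    rng = np.random.default_rng(seed)
    rej = {"student_t": 0, "anova": 0, "one_sample_t": 0, "kruskal_wallis": 0}
    for _ in range(n_sims):
        a, b, c = rng.normal(size=(3, n))
        rej["student_t"] += two_group_test(a, b, kind="student").pvalue < alpha
        rej["anova"] += one_way_anova([a, b, c]).pvalue < alpha
        rej["one_sample_t"] += (
            one_sample_test(rng.normal(loc=1.0, size=n), 1.0).pvalue < alpha
        )
        kw, _ = kw_with_posthoc([a, b, c])
        rej["kruskal_wallis"] += kw.pvalue < alpha
    return {k: v / n_sims for k, v in rej.items()}
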