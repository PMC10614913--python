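"""Ground-truthed synthetic inputs for the pulse-chase turnover pipeline.

Emulates the study design: animals fully 15N-labeled at birth are switched to
a 14N diet, so at a chase timepoint t months later a protein pool turning
over with first-order rate k retains a 15N ("old") fraction

    FA(t) = 100 * exp(-k * t)   [percent]

Three generators are provided:

* :func:`simulate_proteome` — random tryptic-friendly protein sequences with
  per-protein turnover rates drawn from a two-component log-normal mixture: a
  fast majority (median half-life ~3 days, typical of somatic proteins) and a
  slow, long-lived tail (median half-life 12 months). The slow-component flag
  is the long-lived-protein (LLP) ground truth.
* :func:`synthesize_ms1_run` — a centroided MS1 run in which each peptide
  elutes as a Gaussian peak; the light (natural-abundance) envelope carries a
  fraction 1 - FA/100 of the peptide's total area and the heavy envelope (at
  the initial labeling enrichment, default 0.95) carries FA/100. Noise is
  multiplicative log-normal per centroid plus an additive baseline.
* :func:`synthesize_mims_fields` — Poisson multi-channel ion-count images
  (12C14N-, 12C15N-, 31P-) with labeled regions at specified 15N enrichment
  above the 0.37% natural baseline and bright 31P disks marking nuclei.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import MIMS_BASELINE_RATIO, NATURAL_15N
from .isotope_chem import (
    PeptideSpecies,
    isotope_envelope,
    mz_from_mass,
    tryptic_digest,
)
from .quant_ms import Ms1Run

_AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# turnover model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TurnoverModel:
    """Single-pool first-order turnover over the chase period."""

    rate_k: float                 # per month
    chase_months: float
    initial_enrichment: float = 0.95

    def __post_init__(self) -> None:
        if self.rate_k < 0:
            raise ValueError("turnover rate must be >= 0")
        if self.chase_months < 0:
            raise ValueError("chase duration must be >= 0")
        if not 0 <= self.initial_enrichment <= 1:
            raise ValueError("initial enrichment must lie in [0, 1]")


def true_fa(model: TurnoverModel) -> float:
    """Percent of the pool still 15N-labeled: 100 * exp(-k t)."""
    return 100.0 * float(np.exp(-model.rate_k * model.chase_months))


# ---------------------------------------------------------------------------
# proteome simulation
# ---------------------------------------------------------------------------


@dataclass
class ProteomeConfig:
    """Study conditions for the simulated proteome.

    The turnover-rate mixture has a fast majority (median half-life
    ``fast_half_life_months``) and a slow long-lived tail (median
    ``slow_half_life_months``); both components are log-normal with
    ``sigma_ln`` on the half-life scale. ``llp_fraction`` is the slow-
    component weight and defines the LLP ground-truth flag.
    """

    n_proteins: int = 200
    length_range: tuple[int, int] = (240, 600)
    llp_fraction: float = 0.15
    kr_frequency: float = 0.08           # per-residue chance of K or R
    fast_half_life_months: float = 0.1   # ~3 days
    slow_half_life_months: float = 12.0
    sigma_ln: float = 0.7
    initial_enrichment: float = 0.95
    timepoints: tuple[float, ...] = (6.0, 10.0)


@dataclass
class SyntheticTruth:
    """Ground truth: per-protein rates, FA per timepoint, LLP flags."""

    table: pd.DataFrame
    seed: int
    config: ProteomeConfig

    def fa_column(self, timepoint: float) -> str:
        return f"fa_{timepoint:g}"

    def true_fa(self, protein_id: str, timepoint: float) -> float:
        row = self.table.loc[self.table["protein_id"] == protein_id]
        return float(row[self.fa_column(timepoint)].iloc[0])


def _random_sequence(rng: np.random.Generator, length: int, kr_freq: float) -> str:
    others = [aa for aa in _AA if aa not in "KR"]
    p = np.full(len(_AA), 0.0)
    for aa in "KR":
        p[_AA.index(aa)] = kr_freq / 2
    for aa in others:
        p[_AA.index(aa)] = (1 - kr_freq) / len(others)
    idx = rng.choice(len(_AA), size=length, p=p)
    return "".join(_AA[i] for i in idx)


def simulate_proteome(
    config: ProteomeConfig = ProteomeConfig(), seed: int = 0
) -> tuple[dict[str, str], SyntheticTruth]:
    """Random proteome plus turnover ground truth.

    Returns ``(sequences, truth)``; ``sequences`` maps protein id to sequence.
    """
    if config.n_proteins < 1:
        raise ValueError("need at least one protein")
    if not 0 <= config.llp_fraction <= 1:
        raise ValueError("llp_fraction must lie in [0, 1]")
    lo, hi = config.length_range
    if lo >= hi or lo < 20:
        raise ValueError(f"degenerate length distribution {config.length_range}")
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    rows = []
    ln2 = float(np.log(2.0))
    for i in range(config.n_proteins):
        pid = f"SYN{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        sequences[pid] = _random_sequence(rng, length, config.kr_frequency)
        is_llp = bool(rng.random() < config.llp_fraction)
        median_hl = (
            config.slow_half_life_months if is_llp else config.fast_half_life_months
        )
        half_life = float(
            median_hl * np.exp(rng.normal(0.0, config.sigma_ln))
        )
        k = ln2 / half_life if half_life > 0 else 0.0
        row = {
            "protein_id": pid,
            "rate_k": k,
            "half_life_months": half_life,
            "is_llp": is_llp,
        }
        for t in config.timepoints:
            row[f"fa_{t:g}"] = true_fa(
                TurnoverModel(k, t, config.initial_enrichment)
            )
        rows.append(row)
    truth = SyntheticTruth(pd.DataFrame(rows), seed, config)
    return sequences, truth


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for pid in sequences:
            fh.write(f">{pid}\n")
            seq = sequences[pid]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# MS1 run synthesis
# ---------------------------------------------------------------------------


@dataclass
class Ms1Params:
    """Acquisition and noise model for the synthetic MS1 run.

    Peaks are Gaussian in elution time (FWHM 0.2 min over a 75-min run,
    mirroring the oocyte gradient length). ``noise_sigma_ln`` is the standard
    deviation of the multiplicative log-normal intensity noise applied per
    centroid, and the additive baseline level is ``baseline_frac`` of the
    maximum signal intensity of the run.
    """

    run_minutes: float = 75.0
    sampling_interval_s: float = 2.0
    fwhm_min: float = 0.2
    charge: int = 2
    intensity_mean: float = 1.0e6       # mean total peptide area
    intensity_sigma_ln: float = 0.5
    noise_sigma_ln: float = 0.1
    baseline_frac: float = 0.005
    peptides_per_protein: int = 5
    timepoint: float = 6.0
    min_peak_prob: float = 0.01         # envelope peaks below this are not emitted

    @classmethod
    def noiseless(cls, **kw) -> "Ms1Params":
        return cls(noise_sigma_ln=0.0, baseline_frac=0.0, **kw)


@dataclass
class SyntheticMs1Run:
    """A synthetic run plus the per-peptide truth needed to audit recovery."""

    run: Ms1Run
    peptides: pd.DataFrame   # protein, peptide, charge, rt_min, true_fa, areas
    params: Ms1Params
    seed: int

    def identifications(self) -> pd.DataFrame:
        """The identification table a search engine would have produced."""
        return self.peptides[["peptide", "protein", "charge", "rt_min"]].copy()


def select_peptides(
    sequences: dict[str, str], per_protein: int, min_nitrogen: int = 6
) -> list[tuple[str, PeptideSpecies]]:
    """First few digest peptides per protein (deterministic, unique masses)."""
    out = []
    for pid, seq in sequences.items():
        peps = tryptic_digest(seq)
        chosen = []
        seen = set()
        for p in peps:
            if p.sequence in seen or p.n_nitrogen < min_nitrogen:
                continue
            seen.add(p.sequence)
            chosen.append(p)
            if len(chosen) >= per_protein:
                break
        out.extend((pid, p) for p in chosen)
    return out


def synthesize_ms1_run(
    peptides: Sequence[tuple[str, PeptideSpecies]],
    truth: SyntheticTruth,
    params: Ms1Params = Ms1Params(),
    seed: int = 0,
) -> SyntheticMs1Run:
    """Build a centroided MS1 run containing paired light/heavy envelopes.

    For each peptide the light envelope (natural abundance) receives a
    fraction ``1 - FA/100`` of the peptide's total area and the heavy
    envelope (at the configured initial enrichment) receives ``FA/100``,
    where FA is the protein's true fractional abundance at the requested
    chase timepoint.
    """
    if params.sampling_interval_s <= 0:
        raise ValueError("sampling interval must be positive")
    rng = np.random.default_rng(seed)
    truth_idx = truth.table.set_index("protein_id")
    fa_col = truth.fa_column(params.timepoint)
    if fa_col not in truth.table.columns:
        raise ValueError(f"timepoint {params.timepoint} not in truth table")
    known = set(truth_idx.index)
    for pid, _ in peptides:
        if pid not in known:
            raise ValueError(f"peptide maps to unknown protein {pid!r}")

    dt = params.sampling_interval_s / 60.0
    rts = np.arange(0.0, params.run_minutes, dt)
    n_scans = len(rts)
    sigma = params.fwhm_min / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    scan_mz: list[list[np.ndarray]] = [[] for _ in range(n_scans)]
    scan_int: list[list[np.ndarray]] = [[] for _ in range(n_scans)]
    rows = []
    e0 = truth.config.initial_enrichment

    for pid, pep in peptides:
        fa = float(truth_idx.loc[pid, fa_col])
        rt_apex = float(rng.uniform(5.0, params.run_minutes - 5.0))
        total_area = float(
            params.intensity_mean
            * np.exp(rng.normal(0.0, params.intensity_sigma_ln))
        )
        light_area = total_area * (1.0 - fa / 100.0)
        heavy_area = total_area * (fa / 100.0)

        peaks = []  # (mz, per-scan area weight)
        for area, enrich in ((light_area, NATURAL_15N), (heavy_area, e0)):
            env = isotope_envelope(pep.composition, enrich)
            for off, prob in zip(env.mass_offsets, env.probabilities):
                if prob < params.min_peak_prob:
                    continue
                mz = mz_from_mass(pep.mass_light + off, params.charge)
                peaks.append((mz, area * prob))

        lo = int(np.searchsorted(rts, rt_apex - 4 * sigma))
        hi = int(np.searchsorted(rts, rt_apex + 4 * sigma))
        if hi - lo < 2:
            continue
        window = rts[lo:hi]
        gauss = np.exp(-0.5 * ((window - rt_apex) / sigma) ** 2) / (
            sigma * np.sqrt(2.0 * np.pi)
        )
        mz_arr = np.array([p[0] for p in peaks])
        area_arr = np.array([p[1] for p in peaks])
        for j, g in enumerate(gauss):
            scan_mz[lo + j].append(mz_arr)
            scan_int[lo + j].append(area_arr * g)
        rows.append(
            {
                "protein": pid,
                "peptide": pep.sequence,
                "charge": params.charge,
                "rt_min": rt_apex,
                "true_fa": fa,
                "light_area": light_area,
                "heavy_area": heavy_area,
            }
        )

    mzs, intens = [], []
    max_signal = 0.0
    for i in range(n_scans):
        if scan_mz[i]:
            mz = np.concatenate(scan_mz[i])
            inten = np.concatenate(scan_int[i])
            if len(inten):
                max_signal = max(max_signal, float(inten.max()))
        else:
            mz = np.empty(0)
            inten = np.empty(0)
        mzs.append(mz)
        intens.append(inten)

    baseline = params.baseline_frac * max_signal
    for i in range(n_scans):
        inten = intens[i]
        if len(inten) == 0:
            continue
        if params.noise_sigma_ln > 0:
            inten = inten * np.exp(
                rng.normal(0.0, params.noise_sigma_ln, size=len(inten))
            )
            if baseline > 0:
                inten = inten + baseline * np.exp(
                    rng.normal(0.0, params.noise_sigma_ln, size=len(inten))
                )
        elif baseline > 0:
            inten = inten + baseline
        intens[i] = inten

    run = Ms1Run(rts, mzs, intens)
    return SyntheticMs1Run(run, pd.DataFrame(rows), params, seed)


def load_generation_config(path: str | Path) -> tuple[ProteomeConfig, Ms1Params, int]:
    """Read a YAML generation config: proteome/ms1 sections plus a seed.

    Unknown keys are rejected so a typo cannot silently fall back to a
    default. The seed is mandatory — generated datasets must be reproducible.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "seed" not in raw:
        raise ValueError("generation config must set an explicit seed")
    seed = int(raw["seed"])

    def build(cls, section):
        data = raw.get(section, {}) or {}
        allowed = set(cls.__dataclass_fields__)
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown keys in {section!r}: {sorted(unknown)}")
        for key in ("length_range", "timepoints"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    return build(ProteomeConfig, "proteome"), build(Ms1Params, "ms1"), seed


def write_run_bundle(directory: str | Path, synth: SyntheticMs1Run) -> None:
    """Chromatogram TSV + identification TSV + truth TSV + JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    synth.run.to_tsv(directory / "ms1_run.tsv")
    synth.identifications().to_csv(directory / "identifications.tsv", sep="\t", index=False)
    synth.peptides.to_csv(directory / "peptide_truth.tsv", sep="\t", index=False)
    sidecar = {"seed": synth.seed, "params": asdict(synth.params)}
    (directory / "run_params.json").write_text(json.dumps(sidecar, indent=2))


# ---------------------------------------------------------------------------
# MIMS ion-image synthesis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionSpec:
    """A labeled image region at a given 15N level.

    ``percent_above`` is percent above the natural-abundance baseline, so the
    region's 15N/14N ratio is baseline * (1 + percent_above/100).
    ``geometry`` is ("disk", row, col, radius) or ("rect", r0, c0, r1, c1)
    with exclusive upper bounds. ``is_nucleus`` marks regions rendered bright
    in the 31P channel.
    """

    label: int
    percent_above: float
    geometry: tuple
    class_tag: str = ""
    is_nucleus: bool = False


@dataclass
class IonImageStack:
    """Simultaneously acquired 12C14N-, 12C15N- and 31P- count images."""

    n14: np.ndarray
    n15: np.ndarray
    p31: np.ndarray
    pixel_size_um: float = 0.1
    labels: np.ndarray | None = None
    region_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not (self.n14.shape == self.n15.shape == self.p31.shape):
            raise ValueError("channel shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.n14.shape

    def to_tiff(self, path: str | Path) -> None:
        import tifffile

        stack = np.stack([self.n14, self.n15, self.p31]).astype(np.uint32)
        tifffile.imwrite(
            path,
            stack,
            photometric="minisblack",
            metadata={"axes": "CYX", "Channel": {"Name": ["12C14N", "12C15N", "31P"]}},
        )

    @classmethod
    def from_tiff(cls, path: str | Path, pixel_size_um: float = 0.1) -> "IonImageStack":
        import tifffile

        stack = tifffile.imread(path)
        if stack.ndim != 3 or stack.shape[0] != 3:
            raise ValueError("expected a 3-channel (C, Y, X) stack")
        return cls(stack[0], stack[1], stack[2], pixel_size_um)


def _paint_region(mask: np.ndarray, spec: RegionSpec) -> np.ndarray:
    sel = np.zeros(mask.shape, dtype=bool)
    kind = spec.geometry[0]
    if kind == "disk":
        _, r, c, rad = spec.geometry
        rr, cc = np.ogrid[: mask.shape[0], : mask.shape[1]]
        sel = (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
    elif kind == "annulus":
        _, r, c, rad_in, rad_out = spec.geometry
        rr, cc = np.ogrid[: mask.shape[0], : mask.shape[1]]
        d2 = (rr - r) ** 2 + (cc - c) ** 2
        sel = (d2 > rad_in**2) & (d2 <= rad_out**2)
    elif kind == "rect":
        _, r0, c0, r1, c1 = spec.geometry
        sel[r0:r1, c0:c1] = True
    else:
        raise ValueError(f"unknown geometry {kind!r}")
    if (mask[sel] != 0).any():
        raise ValueError(f"region label {spec.label} overlaps an earlier region")
    mask[sel] = spec.label
    return sel


def synthesize_mims_fields(
    shape: tuple[int, int],
    regions: Sequence[RegionSpec],
    mean_14n_counts: float = 10_000.0,
    baseline: float = MIMS_BASELINE_RATIO,
    p31_nucleus_counts: float = 2000.0,
    p31_background_counts: float = 50.0,
    seed: int = 0,
) -> IonImageStack:
    """Poisson ion-count images with regions at specified 15N enrichment.

    Per pixel, 14N counts ~ Poisson(dose) and 15N counts ~ Poisson(dose *
    ratio) where the ratio is the baseline scaled by the region's percent
    above background (baseline outside any region). The 31P channel is bright
    inside regions flagged as nuclei.
    """
    if mean_14n_counts < 0:
        raise ValueError("mean counts must be >= 0")
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int32)
    ratio = np.full(shape, baseline, dtype=float)
    p31_lam = np.full(shape, p31_background_counts, dtype=float)
    rows = []
    for spec in regions:
        if spec.percent_above < -100:
            raise ValueError("percent above background cannot go below -100")
        sel = _paint_region(labels, spec)
        ratio[sel] = baseline * (1.0 + spec.percent_above / 100.0)
        if spec.is_nucleus:
            p31_lam[sel] = p31_nucleus_counts
        rows.append(
            {
                "label": spec.label,
                "class_tag": spec.class_tag,
                "percent_above": spec.percent_above,
                "is_nucleus": spec.is_nucleus,
                "n_pixels": int(sel.sum()),
            }
        )
    n14 = rng.poisson(mean_14n_counts, size=shape).astype(np.uint32)
    n15 = rng.poisson(mean_14n_counts * ratio).astype(np.uint32)
    p31 = rng.poisson(p31_lam).astype(np.uint32)
    return IonImageStack(
        n14, n15, p31, labels=labels, region_truth=pd.DataFrame(rows)
    )


def cell_field_layout(
    n_cells: int,
    shape: tuple[int, int],
    cell_radius: int = 14,
    nucleus_radius: int = 6,
    cyto_percent_above: float = 100.0,
    nucleus_ratio_multiplier: float = 2.0,
) -> list[RegionSpec]:
    """Disjoint nucleus + cytoplasm regions for n cells on a regular grid.

    The nucleus disk sits inside an annular cytoplasm; its 15N/14N ratio is
    ``nucleus_ratio_multiplier`` times the cytoplasmic ratio. Cytoplasm
    labels are 1..n, nucleus labels 1001..1000+n.
    """
    specs = []
    pitch = 2 * cell_radius + 6
    per_row = max(1, (shape[1] - pitch // 2) // pitch)
    cyto_ratio_pct = cyto_percent_above
    nuc_pct = (1.0 + cyto_percent_above / 100.0) * nucleus_ratio_multiplier * 100.0 - 100.0
    for i in range(n_cells):
        r = cell_radius + 3 + (i // per_row) * pitch
        c = cell_radius + 3 + (i % per_row) * pitch
        if r + cell_radius >= shape[0] or c + cell_radius >= shape[1]:
            raise ValueError("field too small for requested cell count")
        specs.append(
            RegionSpec(
                1000 + i + 1, nuc_pct, ("disk", r, c, nucleus_radius),
                class_tag="nucleus", is_nucleus=True,
            )
        )
        specs.append(
            RegionSpec(
                i + 1, cyto_ratio_pct, ("annulus", r, c, nucleus_radius, cell_radius),
                class_tag="cytoplasm",
            )
        )
    return specs
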