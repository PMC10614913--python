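"""Peptide-level light/heavy quantification from MS1 chromatograms.

Given an MS1 run and an identified peptide, the quantifier extracts paired
extracted-ion chromatograms (XICs) for the light (all-14N) and heavy
(all-15N) species, then derives the Census-style metrics the long-lived
protein filter cascade acts on:

* AR — the heavy/light area ratio, estimated as the slope of a
  least-squares fit of heavy on light intensities through the origin;
* r — the Pearson correlation of the paired intensities (the "correlation
  coefficient", gate at 0.5);
* APE — average peptide enrichment: the 15N fraction of the nitrogen pool
  fitted from the observed heavy isotopologue envelope (gate at 0.9);
* profile score — agreement of the observed envelope with theory (gate 0.8);
* singleton analysis — peptides detectable in only one channel are accepted
  when the dominant/minor area ratio exceeds 5.0 and the dominant envelope
  matches theory with score above 0.5.

Intensities summed over the top isotopologues are divided by the summed
theoretical probabilities of those isotopologues ("capture-fraction"
correction) so that the area ratio estimates the full heavy/light pool ratio
even though only part of each envelope is integrated.
"""

from __future__ import annotations

import base64
import math
import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .isotope_chem import (
    ElementalComposition,
    IsotopeEnvelope,
    PeptideSpecies,
    isotope_envelope,
    mz_from_mass,
    peptide_species,
)
from .constants import NATURAL_15N


# ---------------------------------------------------------------------------
# MS1 run container
# ---------------------------------------------------------------------------


class Ms1Run:
    """A centroided MS1 run indexed by retention time and m/z.

    Scans are stored as parallel arrays sorted by m/z within each scan so
    window sums are O(log n) per scan.
    """

    def __init__(self, rts: np.ndarray, mzs: list[np.ndarray], intensities: list[np.ndarray]):
        order = np.argsort(rts, kind="stable")
        self.rts = np.asarray(rts, dtype=float)[order]
        self.mzs = []
        self.intensities = []
        for i in order:
            mz = np.asarray(mzs[i], dtype=float)
            inten = np.asarray(intensities[i], dtype=float)
            srt = np.argsort(mz)
            self.mzs.append(mz[srt])
            self.intensities.append(inten[srt])

    def __len__(self) -> int:
        return len(self.rts)

    def scan_indices(self, rt_lo: float, rt_hi: float) -> np.ndarray:
        lo = np.searchsorted(self.rts, rt_lo, side="left")
        hi = np.searchsorted(self.rts, rt_hi, side="right")
        return np.arange(lo, hi)

    def window_sums(
        self, scan_idx: np.ndarray, mz_lo: np.ndarray, mz_hi: np.ndarray
    ) -> np.ndarray:
        """Summed intensity per (scan, window); windows given as arrays."""
        out = np.zeros((len(mz_lo), len(scan_idx)))
        for j, i in enumerate(scan_idx):
            mz, inten = self.mzs[i], self.intensities[i]
            lo = np.searchsorted(mz, mz_lo, side="left")
            hi = np.searchsorted(mz, mz_hi, side="right")
            csum = np.concatenate([[0.0], np.cumsum(inten)])
            out[:, j] = csum[hi] - csum[lo]
        return out

    def max_intensity(self) -> float:
        return max((float(v.max()) if len(v) else 0.0 for v in self.intensities), default=0.0)

    # -- plain-text serialisation ------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Long-format chromatogram table: scan, rt_min, mz, intensity."""
        with open(path, "w") as fh:
            fh.write("scan\trt_min\tmz\tintensity\n")
            for i, rt in enumerate(self.rts):
                for mz, inten in zip(self.mzs[i], self.intensities[i]):
                    fh.write(f"{i}\t{rt:.6f}\t{mz:.6f}\t{inten:.4f}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Ms1Run":
        df = pd.read_csv(path, sep="\t", comment="#")
        rts, mzs, intens = [], [], []
        for _, grp in df.groupby("scan", sort=True):
            rts.append(grp["rt_min"].iloc[0])
            mzs.append(grp["mz"].to_numpy())
            intens.append(grp["intensity"].to_numpy())
        return cls(np.array(rts), mzs, intens)


def _decode_binary_array(node, ns: str) -> np.ndarray | None:
    accs = {c.get("accession") for c in node.findall(f"{ns}cvParam")}
    dtype = "<f8" if "MS:1000523" in accs else "<f4"
    binary = node.find(f"{ns}binary")
    raw = base64.b64decode(binary.text or "")
    if "MS:1000574" in accs:  # zlib compression
        raw = zlib.decompress(raw)
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    if "MS:1000514" in accs:
        return ("mz", values)
    if "MS:1000515" in accs:
        return ("intensity", values)
    return None


def read_ms1_mzml(path: str | Path) -> Ms1Run:
    """Read centroided MS1 spectra from an mzML file into an :class:`Ms1Run`.

    A deliberately small reader: MS1 spectra only, 32/64-bit float arrays,
    zlib or no compression, retention times taken from the scan start time
    (seconds converted to minutes when the unit says so).
    """
    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"
    rts, mzs, intens = [], [], []
    for _, spec in etree.iterparse(str(path), tag=f"{ns}spectrum"):
        level = None
        for cv in spec.findall(f"{ns}cvParam"):
            if cv.get("accession") == "MS:1000511":
                level = int(cv.get("value"))
        if level not in (None, 1):
            spec.clear()
            continue
        rt = 0.0
        scan_list = spec.find(f"{ns}scanList")
        if scan_list is not None:
            for cv in scan_list.iter(f"{ns}cvParam"):
                if cv.get("accession") == "MS:1000016":
                    rt = float(cv.get("value"))
                    if cv.get("unitName") == "second":
                        rt /= 60.0
        arrays = {}
        for arr in spec.iter(f"{ns}binaryDataArray"):
            decoded = _decode_binary_array(arr, ns)
            if decoded is not None:
                arrays[decoded[0]] = decoded[1]
        if "mz" in arrays and "intensity" in arrays:
            rts.append(rt)
            mzs.append(arrays["mz"])
            intens.append(arrays["intensity"])
        spec.clear()
    return Ms1Run(np.array(rts), mzs, intens)


def read_identification_table(path: str | Path) -> pd.DataFrame:
    """Identification TSV with columns peptide, protein, charge, rt_min."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"peptide", "protein", "charge", "rt_min"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"identification table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# configuration and result records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuantConfig:
    """Extraction and scoring parameters.

    ``extraction_enrichment`` is the 15N enrichment assumed for the heavy
    envelope (the labeling completeness at chase start); 0.95 by default.
    """

    mz_tolerance_ppm: float = 30.0
    rt_half_window_min: float = 1.0
    n_iso_quant: int = 3       # top isotopologues summed per channel
    n_iso_envelope: int = 9    # heavy isotopologues observed for APE / profile
    extraction_enrichment: float = 0.95
    min_points: int = 5
    singleton_ratio: float = 5.0
    singleton_score: float = 0.5
    singleton_on_dominant: bool = True  # apply ratio gate to dominant/minor
    ar_orientation: str = "heavy_over_light"  # or "light_over_heavy"
    estimator: str = "lsq"     # "lsq" slope through origin, or "gmr"
    ape_grid_step: float = 0.001


@dataclass
class XicPair:
    """Paired light/heavy extracted-ion chromatograms on a shared RT grid."""

    peptide: PeptideSpecies
    protein_id: str
    charge: int
    rts: np.ndarray
    light_traces: np.ndarray      # (n_iso_light, n_scans)
    heavy_traces: np.ndarray      # (n_iso_heavy, n_scans)
    light_shifts: np.ndarray      # neutron shifts of the light isotopologues
    heavy_shifts: np.ndarray
    light_probs: np.ndarray       # theoretical probabilities at those shifts
    heavy_probs: np.ndarray
    light_windows: np.ndarray     # (n_iso, 2) m/z windows used
    heavy_windows: np.ndarray
    n_quant: int = 3

    def _summed(self, traces, probs) -> np.ndarray:
        k = min(self.n_quant, traces.shape[0])
        top = np.argsort(probs)[::-1][:k]
        capture = probs[top].sum()
        if capture <= 0:
            return np.zeros(traces.shape[1])
        return traces[top].sum(axis=0) / capture

    @property
    def light(self) -> np.ndarray:
        """Capture-corrected summed light trace."""
        return self._summed(self.light_traces, self.light_probs)

    @property
    def heavy(self) -> np.ndarray:
        return self._summed(self.heavy_traces, self.heavy_probs)


@dataclass
class PeptideQuantRecord:
    """Per-peptide quantification result feeding the filter cascade."""

    peptide: str
    protein_id: str
    charge: int
    ar: float = math.nan               # heavy/light area ratio
    r: float = math.nan                # regression correlation
    ape: float = math.nan              # estimated 15N enrichment
    profile_score: float = math.nan
    is_singleton: bool = False
    singleton_score: float = math.nan
    dominant_channel: str = ""         # "light" | "heavy"
    ar_infinite: bool = False          # heavy signal with no light partner
    light_area: float = 0.0
    heavy_area: float = 0.0
    n_points: int = 0
    flags: list[str] = field(default_factory=list)
    valid: bool = True
    reject_reason: str = ""


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def extract_xic_pair(
    run: Ms1Run,
    peptide: PeptideSpecies,
    charge: int,
    rt_window: tuple[float, float],
    config: QuantConfig = QuantConfig(),
    protein_id: str = "",
) -> XicPair:
    """Extract per-isotopologue light and heavy XICs for one peptide.

    The light windows are centred on the top isotopologues of the natural-
    abundance envelope; the heavy windows on the envelope at the configured
    extraction enrichment. Window half-width is ``mz_tolerance_ppm``.
    """
    idx = run.scan_indices(*rt_window)
    if len(idx) == 0:
        warnings.warn(
            f"rt window {rt_window} outside run range; empty XIC for {peptide.sequence}"
        )
    light_env = isotope_envelope(peptide.composition, NATURAL_15N)
    heavy_env = isotope_envelope(
        peptide.composition, config.extraction_enrichment
    )

    def top_peaks(env: IsotopeEnvelope, k: int):
        order = np.argsort(env.probabilities)[::-1][:k]
        order = np.sort(order)
        return env.neutron_shifts[order], env.mass_offsets[order], env.probabilities[order]

    l_shift, l_off, l_prob = top_peaks(light_env, config.n_iso_quant)
    h_shift, h_off, h_prob = top_peaks(heavy_env, config.n_iso_envelope)

    def windows(mass_base: float, offsets: np.ndarray):
        mz = np.array([mz_from_mass(mass_base + o, charge) for o in offsets])
        tol = mz * config.mz_tolerance_ppm * 1e-6
        return np.column_stack([mz - tol, mz + tol])

    lw = windows(peptide.mass_light, l_off)
    hw = windows(peptide.mass_light, h_off)  # offsets are from light mono

    lt = run.window_sums(idx, lw[:, 0], lw[:, 1]) if len(idx) else np.zeros((len(lw), 0))
    ht = run.window_sums(idx, hw[:, 0], hw[:, 1]) if len(idx) else np.zeros((len(hw), 0))
    return XicPair(
        peptide=peptide,
        protein_id=protein_id,
        charge=charge,
        rts=run.rts[idx],
        light_traces=lt,
        heavy_traces=ht,
        light_shifts=l_shift,
        heavy_shifts=h_shift,
        light_probs=l_prob,
        heavy_probs=h_prob,
        light_windows=lw,
        heavy_windows=hw,
        n_quant=config.n_iso_quant,
    )


# ---------------------------------------------------------------------------
# trace utilities
# ---------------------------------------------------------------------------


def baseline_estimate(trace: np.ndarray) -> float:
    """Median of the lowest-decile intensities (per-trace baseline).

    Computed over detected (positive) centroids only: in a centroided run a
    zero means no peak was picked in the window, not a zero-intensity peak.
    """
    pos = trace[trace > 0]
    if pos.size == 0:
        return 0.0
    k = max(1, pos.size // 10)
    low = np.partition(pos, k - 1)[:k]
    return float(np.median(low))


def _above_baseline(trace: np.ndarray, baseline: float) -> np.ndarray:
    if baseline <= 0:
        return trace > 0
    return trace > 2.0 * baseline


def integrate_trace(rts: np.ndarray, trace: np.ndarray, baseline: float,
                    region: np.ndarray | None = None) -> float:
    """Trapezoidal area of (trace - baseline) over a contiguous region.

    When ``region`` is None it is the contiguous above-baseline stretch
    around the trace apex.
    """
    if trace.size < 2:
        return 0.0
    if region is None:
        mask = _above_baseline(trace, baseline)
        if not mask.any():
            return 0.0
        apex = int(np.argmax(trace))
        if not mask[apex]:
            apex = int(np.argmax(np.where(mask, trace, -np.inf)))
        lo = apex
        while lo > 0 and mask[lo - 1]:
            lo -= 1
        hi = apex
        while hi < len(trace) - 1 and mask[hi + 1]:
            hi += 1
        region = np.arange(lo, hi + 1)
    if len(region) < 2:
        return 0.0
    y = np.clip(trace[region] - baseline, 0.0, None)
    return float(np.trapezoid(y, rts[region]))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def regression_ratio(
    xic: XicPair, config: QuantConfig = QuantConfig()
) -> tuple[float, float, int]:
    """Area ratio and correlation from paired co-eluting intensities.

    Returns ``(AR, r, n_points)``. AR is the least-squares slope of heavy on
    light through the origin (the channels share a prior baseline
    subtraction); r is the Pearson correlation of the paired intensities.
    Fewer than ``config.min_points`` qualifying points raises
    :class:`InsufficientPointsError` so callers can route the peptide to
    singleton analysis.
    """
    light, heavy = xic.light, xic.heavy
    bl, bh = baseline_estimate(light), baseline_estimate(heavy)
    ml = _above_baseline(light, bl)
    mh = _above_baseline(heavy, bh)
    mask = ml & mh
    n = int(mask.sum())
    if n < config.min_points:
        raise InsufficientPointsError(n)
    x = light[mask] - bl
    y = heavy[mask] - bh
    if config.ar_orientation == "light_over_heavy":
        x, y = y, x
    if config.estimator == "gmr":
        denom = float(np.dot(x, x))
        num = float(np.dot(y, y))
        ar = math.sqrt(num / denom) if denom > 0 else math.inf
    else:
        denom = float(np.dot(x, x))
        ar = float(np.dot(x, y)) / denom if denom > 0 else math.inf
    if np.std(x) == 0 or np.std(y) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    return max(ar, 0.0), r, n


class InsufficientPointsError(Exception):
    """Fewer co-eluting points than the regression minimum."""

    def __init__(self, n: int):
        super().__init__(f"only {n} qualifying points")
        self.n = n


def estimate_enrichment(
    observed: np.ndarray,
    composition: ElementalComposition,
    neutron_shifts: Sequence[int] | None = None,
    grid_step: float = 0.001,
    grid_range: tuple[float, float] = (NATURAL_15N, 1.0),
) -> tuple[float, float]:
    """APE: the 15N enrichment whose theoretical envelope best matches.

    Maximises cosine similarity between ``observed`` isotopologue intensities
    (indexed by ``neutron_shifts``; default 0..len-1) and theoretical
    envelopes over an enrichment grid. Only the nitrogen distribution depends
    on the enrichment, so the nitrogen-free part is convolved once.

    Returns ``(ape, best_similarity)``.
    """
    observed = np.asarray(observed, dtype=float)
    if observed.size < 3:
        raise ValueError("need at least 3 observed isotopologue intensities")
    if not np.any(observed > 0):
        raise ValueError("all-zero observation; enrichment undefined")
    if neutron_shifts is None:
        neutron_shifts = np.arange(observed.size)
    shifts = np.asarray(neutron_shifts, dtype=int)

    from .isotope_chem import _composition_dist  # nitrogen-free part

    rest = replace(composition, N=0)
    p_rest, _ = _composition_dist(rest, 0.0)
    n_nit = composition.n_nitrogen
    lo, hi = grid_range
    # anchor grid points at multiples of the step so round numbers are exact,
    # and always include both range endpoints
    interior = np.arange(np.ceil(lo / grid_step) * grid_step, hi, grid_step)
    grid = np.unique(np.clip(np.concatenate([[lo], interior, [hi]]), 0.0, 1.0))
    k = np.arange(n_nit + 1)
    # binomial pmf over heavy-nitrogen count for every grid enrichment
    binom = _stats.binom.pmf(k[None, :], n_nit, grid[:, None])
    obs = observed / np.linalg.norm(observed)
    best_e, best_sim = grid[0], -1.0
    for e, row in zip(grid, binom):
        full = np.convolve(row, p_rest)
        theo = np.zeros(len(shifts))
        ok = shifts < len(full)
        theo[ok] = full[shifts[ok]]
        norm = np.linalg.norm(theo)
        if norm == 0:
            continue
        sim = float(np.dot(theo / norm, obs))
        if sim > best_sim:
            best_e, best_sim = float(e), sim
    return best_e, best_sim


def profile_score(
    observed: np.ndarray, theoretical: np.ndarray
) -> tuple[float, bool]:
    """Pearson correlation of observed vs theoretical envelope, clipped to [0,1].

    Returns ``(score, degenerate)`` where ``degenerate`` marks a constant
    observed vector (score forced to 0).
    """
    observed = np.asarray(observed, dtype=float)
    theoretical = np.asarray(theoretical, dtype=float)
    if observed.shape != theoretical.shape:
        raise ValueError("observed and theoretical envelopes differ in length")
    if np.std(observed) == 0 or np.std(theoretical) == 0:
        return 0.0, True
    r = float(np.corrcoef(observed, theoretical)[0, 1])
    return float(np.clip(r, 0.0, 1.0)), False


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def singleton_analysis(
    xic: XicPair,
    ratio_threshold: float = 5.0,
    score_threshold: float = 0.5,
) -> tuple[bool, float, str]:
    """Classify a one-channel peptide.

    A peptide is a singleton when the dominant channel's integrated area
    exceeds ``ratio_threshold`` times the minor channel's. It is *accepted*
    when the dominant channel's observed isotopologue envelope matches theory
    with cosine similarity above ``score_threshold``.

    Returns ``(is_singleton, singleton_score, dominant_channel)``; the score
    is reported whether or not the ratio gate passed.
    """
    light, heavy = xic.light, xic.heavy
    bl, bh = baseline_estimate(light), baseline_estimate(heavy)
    area_l = integrate_trace(xic.rts, light, bl)
    area_h = integrate_trace(xic.rts, heavy, bh)
    if area_l <= 0 and area_h <= 0:
        return False, 0.0, ""
    dominant = "heavy" if area_h > area_l else "light"
    dom, minor = max(area_l, area_h), min(area_l, area_h)
    ratio = math.inf if minor <= 0 else dom / minor
    is_singleton = ratio > ratio_threshold
    if dominant == "heavy":
        traces, probs = xic.heavy_traces, xic.heavy_probs
    else:
        traces, probs = xic.light_traces, xic.light_probs
    obs = _observed_envelope(xic.rts, traces)
    score = cosine_similarity(obs, probs)
    return is_singleton, score, dominant


def _observed_envelope(rts: np.ndarray, traces: np.ndarray) -> np.ndarray:
    """Per-isotopologue integrated areas (shared elution region, shared baseline)."""
    total = traces.sum(axis=0)
    b = baseline_estimate(total)
    mask = _above_baseline(total, b)
    if not mask.any() or traces.shape[1] < 2:
        return traces.sum(axis=1)
    apex = int(np.argmax(np.where(mask, total, -np.inf)))
    lo = apex
    while lo > 0 and mask[lo - 1]:
        lo -= 1
    hi = apex
    while hi < traces.shape[1] - 1 and mask[hi + 1]:
        hi += 1
    region = np.arange(lo, hi + 1)
    out = np.empty(traces.shape[0])
    for i in range(traces.shape[0]):
        tb = baseline_estimate(traces[i])
        out[i] = integrate_trace(rts, traces[i], tb, region=region)
    return out


# ---------------------------------------------------------------------------
# per-peptide quantification driver
# ---------------------------------------------------------------------------


def quantify_xic(
    xic: XicPair, config: QuantConfig = QuantConfig()
) -> PeptideQuantRecord:
    """Full quantification of one extracted peptide.

    Routes the peptide to regression or singleton analysis, estimates APE and
    the profile score from the heavy envelope, and records the first failure
    reason for peptides that cannot be quantified at all.
    """
    rec = PeptideQuantRecord(
        peptide=xic.peptide.sequence, protein_id=xic.protein_id, charge=xic.charge
    )
    light, heavy = xic.light, xic.heavy
    bl, bh = baseline_estimate(light), baseline_estimate(heavy)
    rec.light_area = integrate_trace(xic.rts, light, bl)
    rec.heavy_area = integrate_trace(xic.rts, heavy, bh)
    if rec.light_area <= 0 and rec.heavy_area <= 0:
        rec.valid = False
        rec.reject_reason = "no signal in either channel"
        return rec

    rec.dominant_channel = "heavy" if rec.heavy_area > rec.light_area else "light"

    try:
        ar, r, n = regression_ratio(xic, config)
        rec.ar, rec.r, rec.n_points = ar, r, n
    except InsufficientPointsError:
        # one-channel peptide: singleton analysis
        is_single, s_score, dominant = singleton_analysis(
            xic, config.singleton_ratio, config.singleton_score
        )
        rec.is_singleton = True
        rec.singleton_score = s_score
        rec.dominant_channel = dominant
        if not is_single:
            rec.valid = False
            rec.reject_reason = "below singleton ratio with insufficient points"
            return rec
        if dominant == "heavy":
            rec.ar_infinite = True
            rec.ar = math.inf
        else:
            rec.ar = 0.0

    # heavy-envelope shape metrics (APE, profile score)
    obs_heavy = _observed_envelope(xic.rts, xic.heavy_traces)
    if np.any(obs_heavy > 0) and (not rec.is_singleton or dominant == "heavy"):
        try:
            rec.ape, _ = estimate_enrichment(
                obs_heavy,
                xic.peptide.composition,
                xic.heavy_shifts,
                grid_step=config.ape_grid_step,
            )
        except ValueError:
            rec.flags.append("ape_undefined")
        score, degenerate = profile_score(obs_heavy, xic.heavy_probs)
        rec.profile_score = score
        if degenerate:
            rec.flags.append("degenerate_profile")
    else:
        rec.flags.append("no_heavy_envelope")
    return rec


def quantify_run(
    run: Ms1Run,
    identifications: pd.DataFrame | Iterable[dict],
    config: QuantConfig = QuantConfig(),
) -> list[PeptideQuantRecord]:
    """Quantify every identified peptide in a run.

    ``identifications`` rows need ``peptide``, ``protein``, ``charge`` and
    ``rt_min`` (apex retention time, minutes).
    """
    if isinstance(identifications, pd.DataFrame):
        rows = identifications.to_dict("records")
    else:
        rows = list(identifications)
    species_cache: dict[str, PeptideSpecies] = {}
    records = []
    for row in rows:
        seq = row["peptide"]
        sp = species_cache.get(seq)
        if sp is None:
            sp = peptide_species(seq, min_length=1)
            species_cache[seq] = sp
        rt = float(row["rt_min"])
        xic = extract_xic_pair(
            run,
            sp,
            int(row["charge"]),
            (rt - config.rt_half_window_min, rt + config.rt_half_window_min),
            config,
            protein_id=str(row["protein"]),
        )
        records.append(quantify_xic(xic, config))
    return records


def records_to_frame(records: Iterable[PeptideQuantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "peptide": r.peptide,
                "protein": r.protein_id,
                "charge": r.charge,
                "ar": r.ar,
                "r": r.r,
                "ape": r.ape,
                "profile_score": r.profile_score,
                "is_singleton": r.is_singleton,
                "singleton_score": r.singleton_score,
                "dominant_channel": r.dominant_channel,
                "ar_infinite": r.ar_infinite,
                "light_area": r.light_area,
                "heavy_area": r.heavy_area,
                "n_points": r.n_points,
                "valid": r.valid,
                "reject_reason": r.reject_reason,
            }
        )
    return pd.DataFrame(rows)


def write_quant_tsv(
    path: str | Path,
    records: Iterable[PeptideQuantRecord],
    config: QuantConfig = QuantConfig(),
) -> None:
    """Per-peptide quant table; extraction thresholds echoed as # comments."""
    df = records_to_frame(records)
    with open(path, "w") as fh:
        for key, val in vars(config).items() if not hasattr(config, "__dataclass_fields__") else [
            (f, getattr(config, f)) for f in config.__dataclass_fields__
        ]:
            fh.write(f"# {key} = {val}\n")
        df.to_csv(fh, sep="\t", index=False)
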