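"""Light/heavy quantification: XIC extraction, AR regression, APE, scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isopulse.isotope_chem import isotope_envelope, peptide_composition, peptide_species
from isopulse.quant_ms import (
    InsufficientPointsError,
    Ms1Run,
    QuantConfig,
    XicPair,
    cosine_similarity,
    estimate_enrichment,
    extract_xic_pair,
    profile_score,
    quantify_run,
    records_to_frame,
    regression_ratio,
    singleton_analysis,
    write_quant_tsv,
)


def make_xic(light, heavy, rts=None, sequence="PEPTIDEK"):
    """Assemble an XicPair directly from summed-channel traces.

    A single isotopologue per channel with probability 1 makes the summed
    (capture-corrected) traces equal the inputs.
    """
    light = np.asarray(light, dtype=float)
    heavy = np.asarray(heavy, dtype=float)
    rts = np.arange(len(light)) * 0.05 if rts is None else np.asarray(rts)
    sp = peptide_species(sequence)
    one = np.array([1.0])
    return XicPair(
        peptide=sp,
        protein_id="P",
        charge=2,
        rts=rts,
        light_traces=light[None, :],
        heavy_traces=heavy[None, :],
        light_shifts=np.array([0]),
        heavy_shifts=np.array([sp.n_nitrogen]),
        light_probs=one,
        heavy_probs=one,
        light_windows=np.array([[0.0, 1.0]]),
        heavy_windows=np.array([[0.0, 1.0]]),
        n_quant=1,
    )


def gaussian_peak(n=60, apex=30, sigma=6.0, height=1000.0):
    x = np.arange(n)
    return height * np.exp(-0.5 * ((x - apex) / sigma) ** 2)


class TestRegressionRatio:
    def test_exact_proportionality(self):
        light = gaussian_peak()
        xic = make_xic(light, 0.25 * light)
        ar, r, n = regression_ratio(xic)
        assert ar == pytest.approx(0.25, abs=1e-9)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_equal_channels_give_unit_ratio(self):
        light = gaussian_peak()
        ar, r, _ = regression_ratio(make_xic(light, light.copy()))
        assert ar == pytest.approx(1.0, abs=1e-9)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_permuted_trace_fails_correlation_gate(self):
        """A heavy trace that is a random permutation of the light trace
        almost never reaches the 0.5 correlation threshold."""
        rng = np.random.default_rng(7)
        light = gaussian_peak(n=50, apex=25, sigma=5.0)
        passing = 0
        for _ in range(1000):
            heavy = rng.permutation(light)
            _, r, _ = regression_ratio(make_xic(light, heavy))
            if abs(r) < 0.5:
                passing += 1
        assert passing >= 950

    def test_insufficient_points_routes_to_singleton(self):
        light = gaussian_peak()
        heavy = np.zeros_like(light)
        with pytest.raises(InsufficientPointsError):
            regression_ratio(make_xic(light, heavy))

    @given(c=st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=40, derandomize=True)
    def test_scale_invariance(self, c):
        """Multiplying both channels by c > 0 leaves AR and r unchanged."""
        light = gaussian_peak()
        heavy = 0.4 * light
        ar0, r0, _ = regression_ratio(make_xic(light, heavy))
        ar1, r1, _ = regression_ratio(make_xic(c * light, c * heavy))
        assert ar1 == pytest.approx(ar0, rel=1e-9)
        assert r1 == pytest.approx(r0, abs=1e-9)

    def test_swap_symmetry_on_proportional_traces(self):
        light = gaussian_peak()
        heavy = 0.3 * light
        ar, _, _ = regression_ratio(make_xic(light, heavy))
        ar_sw, _, _ = regression_ratio(make_xic(heavy, light))
        assert ar_sw == pytest.approx(1.0 / ar, rel=1e-9)

    def test_gmr_estimator_symmetric_under_noise(self):
        rng = np.random.default_rng(0)
        light = gaussian_peak() * rng.lognormal(0, 0.1, 60)
        heavy = 0.3 * gaussian_peak() * rng.lognormal(0, 0.1, 60)
        cfg = QuantConfig(estimator="gmr")
        ar, _, _ = regression_ratio(make_xic(light, heavy), cfg)
        ar_sw, _, _ = regression_ratio(make_xic(heavy, light), cfg)
        assert ar_sw == pytest.approx(1.0 / ar, rel=1e-9)


class TestEnrichmentEstimate:
    @pytest.mark.parametrize("e", [0.2, 0.5, 0.8, 0.95])
    def test_roundtrip_noiseless(self, e):
        comp = peptide_composition("LNDAGFIKEQTVR")
        env = isotope_envelope(comp, e)
        ape, sim = estimate_enrichment(env.probabilities, comp, env.neutron_shifts)
        assert ape == pytest.approx(e, abs=0.002)
        assert sim > 0.999

    def test_natural_abundance_recovered_at_lower_bound(self):
        comp = peptide_composition("LNDAGFIKEQTVR")
        env = isotope_envelope(comp, 0.0037)
        ape, _ = estimate_enrichment(env.probabilities, comp, env.neutron_shifts)
        assert ape <= 0.01

    def test_full_enrichment_boundary(self):
        comp = peptide_composition("LNDAGFIKEQTVR")
        env = isotope_envelope(comp, 1.0)
        ape, _ = estimate_enrichment(env.probabilities, comp, env.neutron_shifts)
        assert ape == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_generating_enrichment(self):
        comp = peptide_composition("GASPVTKLR")
        apes = []
        for e in (0.2, 0.5, 0.8, 0.95):
            env = isotope_envelope(comp, e)
            ape, _ = estimate_enrichment(env.probabilities, comp, env.neutron_shifts)
            apes.append(ape)
        assert np.all(np.diff(apes) >= 0)

    def test_all_zero_observation_rejected(self):
        comp = peptide_composition("GASPVTK")
        with pytest.raises(ValueError, match="all-zero"):
            estimate_enrichment(np.zeros(5), comp, np.arange(5))

    def test_too_few_points_rejected(self):
        comp = peptide_composition("GASPVTK")
        with pytest.raises(ValueError):
            estimate_enrichment(np.array([1.0, 2.0]), comp, np.arange(2))


class TestProfileScore:
    def test_perfect_match(self):
        theo = np.array([0.1, 0.5, 0.3, 0.1])
        score, degenerate = profile_score(theo, theo)
        assert score == pytest.approx(1.0)
        assert not degenerate

    def test_anticorrelated_clips_to_zero(self):
        theo = np.array([0.1, 0.5, 0.3, 0.1])
        score, _ = profile_score(theo.max() + theo.min() - theo, theo)
        assert score == 0.0

    def test_constant_observation_flagged(self):
        theo = np.array([0.1, 0.5, 0.3, 0.1])
        score, degenerate = profile_score(np.full(4, 2.0), theo)
        assert score == 0.0 and degenerate

    def test_poisson_noise_rarely_breaks_gate(self):
        """At ~10^4 total counts a 5-peak envelope stays above the 0.8
        profile-score gate in almost every draw."""
        rng = np.random.default_rng(11)
        comp = peptide_composition("LNDAGFIKEQTVR")
        env = isotope_envelope(comp, 0.95)
        p = env.probabilities / env.probabilities.sum()
        passing = 0
        for _ in range(1000):
            obs = rng.multinomial(10_000, p).astype(float)
            score, _ = profile_score(obs, env.probabilities)
            if score > 0.8:
                passing += 1
        assert passing >= 990


class TestSingleton:
    def _singleton_xic(self, ratio, sequence="LNDAGFIKEQTVR", enrichment=0.95):
        """Heavy-dominant pair whose heavy envelope follows theory."""
        sp = peptide_species(sequence)
        env = isotope_envelope(sp.composition, enrichment)
        n_rt = 40
        shape = gaussian_peak(n=n_rt, apex=20, sigma=4.0, height=1.0)
        heavy = env.probabilities[:, None] * shape[None, :] * 1e5
        light = gaussian_peak(n=n_rt, apex=20, sigma=4.0, height=1e5 / ratio)
        return XicPair(
            peptide=sp,
            protein_id="P",
            charge=2,
            rts=np.arange(n_rt) * 0.05,
            light_traces=light[None, :],
            heavy_traces=heavy,
            light_shifts=np.array([0]),
            heavy_shifts=env.neutron_shifts,
            light_probs=np.array([1.0]),
            heavy_probs=env.probabilities,
            light_windows=np.zeros((1, 2)),
            heavy_windows=np.zeros((len(env.probabilities), 2)),
            n_quant=len(env.probabilities),
        )

    def test_ratio_six_good_envelope_accepted(self):
        xic = self._singleton_xic(ratio=6.0)
        is_single, score, dominant = singleton_analysis(xic)
        assert is_single and dominant == "heavy"
        assert score > 0.5

    def test_ratio_four_not_a_singleton(self):
        is_single, _, _ = singleton_analysis(self._singleton_xic(ratio=4.0))
        assert not is_single

    def test_good_ratio_bad_envelope_rejected_by_score(self):
        """High dominant/minor ratio but all intensity on the least likely
        isotopologue: the envelope gate must reject it."""
        xic = self._singleton_xic(ratio=20.0)
        distorted = np.zeros_like(xic.heavy_traces)
        worst = int(np.argmin(xic.heavy_probs))
        distorted[worst] = xic.heavy_traces.sum(axis=0)
        xic.heavy_traces = distorted
        is_single, score, _ = singleton_analysis(xic)
        assert is_single
        assert score < 0.5

    def test_both_channels_empty_dropped(self):
        xic = make_xic(np.zeros(30), np.zeros(30))
        is_single, score, dominant = singleton_analysis(xic)
        assert not is_single and dominant == ""

    def test_cosine_similarity_zero_vector(self):
        assert cosine_similarity(np.zeros(3), np.ones(3)) == 0.0


class TestExtraction:
    def test_extracted_areas_match_generator(self, noiseless_run):
        """Noise off: integrated, capture-corrected areas reproduce the
        generator's per-channel areas within 0.5%."""
        from isopulse.quant_ms import baseline_estimate, integrate_trace

        cfg = QuantConfig()
        checked = 0
        for row in noiseless_run.peptides.itertuples():
            if not (10.0 < row.true_fa < 90.0):
                continue
            sp = peptide_species(row.peptide, min_length=1)
            xic = extract_xic_pair(
                noiseless_run.run, sp, row.charge,
                (row.rt_min - 1.0, row.rt_min + 1.0), cfg, row.protein,
            )
            area_l = integrate_trace(xic.rts, xic.light, baseline_estimate(xic.light))
            area_h = integrate_trace(xic.rts, xic.heavy, baseline_estimate(xic.heavy))
            assert area_l == pytest.approx(row.light_area, rel=5e-3)
            assert area_h == pytest.approx(row.heavy_area, rel=5e-3)
            checked += 1
        assert checked >= 5

    def test_empty_window_returns_zero_traces(self, noiseless_run):
        sp = peptide_species("LNDAGFIKEQTVR")
        with pytest.warns(UserWarning, match="outside run range"):
            xic = extract_xic_pair(
                noiseless_run.run, sp, 2, (1e6, 1e6 + 1.0), QuantConfig()
            )
        assert xic.light_traces.size == 0

    def test_distant_decoy_peak_ignored(self):
        """A decoy centroid 10 Da away never enters the ppm windows."""
        sp = peptide_species("LNDAGFIKEQTVR")
        rts = np.arange(20) * 0.05
        mz0 = sp.mz_light(2)
        mzs = [np.array([mz0, mz0 + 10.0]) for _ in rts]
        intens = [np.array([100.0, 5000.0]) for _ in rts]
        run = Ms1Run(rts, mzs, intens)
        xic = extract_xic_pair(run, sp, 2, (0.0, 1.0), QuantConfig())
        assert xic.light_traces[0].max() == pytest.approx(100.0)
        assert xic.light_traces[0].sum() == pytest.approx(100.0 * len(rts))


class TestRunLevel:
    def test_fa_recovery_noiseless(self, noiseless_run):
        """Noise off: FA(AR) equals true FA to 0.1 percentage points."""
        from isopulse.llp_pipeline import fractional_abundance

        records = quantify_run(
            noiseless_run.run, noiseless_run.identifications(), QuantConfig()
        )
        df = records_to_frame(records).merge(
            noiseless_run.peptides, on=["peptide", "protein"]
        )
        ok = df["valid"]
        fa = fractional_abundance(df.loc[ok, "ar"].to_numpy())
        err = np.abs(fa - df.loc[ok, "true_fa"].to_numpy())
        assert err.max() <= 0.1

    def test_fa_recovery_noisy_rmse(self, noisy_records, noisy_run):
        """Default noise: FA RMSE across ~100 peptides stays within 2 points."""
        from isopulse.llp_pipeline import fractional_abundance

        df = records_to_frame(noisy_records).merge(
            noisy_run.peptides, on=["peptide", "protein"]
        )
        ok = df["valid"]
        fa = fractional_abundance(df.loc[ok, "ar"].to_numpy())
        err = fa - df.loc[ok, "true_fa"].to_numpy()
        assert np.sqrt(np.mean(err**2)) <= 2.0

    def test_quant_tsv_includes_thresholds(self, tmp_path, noisy_records):
        out = tmp_path / "quant.tsv"
        write_quant_tsv(out, noisy_records)
        text = out.read_text()
        assert "# singleton_ratio = 5.0" in text
        df = pd.read_csv(out, sep="\t", comment="#")
        assert len(df) == len(noisy_records)


class TestMzmlReader:
    def test_reads_minimal_centroided_ms1(self, tmp_path):
        """Round-trip a hand-built single-spectrum mzML document."""
        import base64
        import struct

        from isopulse.quant_ms import read_ms1_mzml

        mz = [400.1, 400.6, 401.1]
        inten = [10.0, 20.0, 5.0]

        def b64(values):
            return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode()

        doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="r">
    <spectrumList count="1">
      <spectrum index="0" id="scan=1" defaultArrayLength="3">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="12.5" unitName="minute"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="0">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{b64(mz)}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="0">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{b64(inten)}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
    </spectrumList>
  </run>
</mzML>"""
        path = tmp_path / "run.mzML"
        path.write_text(doc)
        run = read_ms1_mzml(path)
        assert len(run) == 1
        assert run.rts[0] == pytest.approx(12.5)
        np.testing.assert_allclose(run.mzs[0], mz)
        np.testing.assert_allclose(run.intensities[0], inten)
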