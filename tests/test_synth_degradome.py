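"""synth_degradome: fragmentation, fractionation, integrity, measurement."""

import dataclasses
import filecmp

import numpy as np
import pytest

from epimark import iodata, quantify, synth_degradome as sd
from epimark.synth_degradome import (
    DEFAULT_WINDOWS,
    NoiseModel,
    default_config,
    default_species,
    expected_integrity,
    expected_mass_in_window,
    fit_cleavage_rate,
    fractionate,
    fragment_distribution,
    integrity_score,
    measure,
    simulate_study,
    synthesize_chromatogram,
    window_concentrations,
)


class TestFragmentDistribution:
    def test_no_cuts_all_mass_at_full_length(self):
        d = fragment_distribution(75, 0.0, 0, 100)
        assert d.mass_nt[75] == 75 * 100
        assert d.mass_nt[:75].sum() == 0

    def test_length_one_degenerate(self):
        d = fragment_distribution(1, 50.0, 0, 100)
        assert d.mass_nt[1] == 100

    def test_mass_conservation_exact(self, rng):
        for L, lam in ((75, 0.5), (1870, 3.0), (4718, 20.0)):
            d = fragment_distribution(L, lam, rng, 5000)
            assert d.mass_nt.sum() == np.int64(L) * 5000

    def test_mass_conservation_property_hypothesis(self):
        """Exact mass conservation for arbitrary lengths and cut rates."""
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=25, derandomize=True, deadline=None)
        @given(st.integers(1, 500), st.floats(0.0, 30.0), st.integers(0, 2**31 - 1))
        def check(L, lam, seed):
            d = fragment_distribution(L, lam, seed, 300)
            assert d.mass_nt.sum() == np.int64(L) * 300
            assert (d.mass_nt >= 0).all()

        check()

    def test_mean_fragment_length_renewal_theory(self):
        """Pooled mean fragment length ~ L/(lambda+1) (Monte-Carlo oracle)."""
        L, lam, n = 4718, 10.0, 10_000
        d = fragment_distribution(L, lam, 1234, n)
        lengths = np.arange(L + 1)
        counts = np.zeros(L + 1)
        counts[1:] = d.mass_nt[1:] / lengths[1:]
        mean_len = d.mass_nt.sum() / counts.sum()
        assert mean_len == pytest.approx(L / (lam + 1), rel=0.05)

    def test_matches_analytic_window_mass(self):
        L, u = 1870, 2e-3
        d = fragment_distribution(L, u * (L - 1), 99, 400_000)
        mc = d.window_mass_fraction(15, 50)
        analytic = expected_mass_in_window(L, u, 15, 50)
        assert mc == pytest.approx(analytic, rel=0.05)


class TestFractionate:
    def setup_method(self):
        self.profiles = {p.name: p for p in default_species("postmortem")}

    def test_undegraded_pool_trna_window_only_trna_species(self):
        dists = {name: fragment_distribution(p.length, 0.0, 0, 1000)
                 for name, p in self.profiles.items()}
        out = fractionate(dists, self.profiles)
        trna_row = out.loc["tRNA"]
        # only species whose intact length lies in 60-75 nt contribute
        assert trna_row["tRNA"] > 0 and trna_row["mito_tRNA"] > 0
        assert trna_row["rRNA18S"] == 0 and trna_row["rRNA28S"] == 0
        assert trna_row["mRNA"] == 0
        assert out.loc["RF"].sum() == 0

    def test_atomized_pool_windows_empty(self):
        dists = {name: fragment_distribution(p.length, p.length * 5.0, 0, 500)
                 for name, p in self.profiles.items()}
        out = fractionate(dists, self.profiles)
        assert out.loc["tRNA"].sum() == pytest.approx(0.0, abs=1e-4)
        assert out.loc["RF"].sum() < 0.05

    def test_rrna_share_of_trna_window_rises_with_degradation(self):
        """Mid-degradation: rRNA-derived mass invades the tRNA-size window."""
        shares = []
        for density in (5e-5, 6.1e-4):  # liver t=0 vs t=8h cut densities
            dists = {
                name: fragment_distribution(
                    p.length, p.susceptibility * density * (p.length - 1),
                    7, 200_000)
                for name, p in self.profiles.items()}
            out = fractionate(dists, self.profiles)
            row = out.loc["tRNA"]
            shares.append((row["rRNA18S"] + row["rRNA28S"]) / row.sum())
        assert shares[1] > shares[0]


class TestIntegrity:
    def setup_method(self):
        self.profiles = {p.name: p for p in default_species("postmortem")}

    def test_intact_pool_scores_ten(self):
        dists = {name: fragment_distribution(p.length, 0.0, 0, 200)
                 for name, p in self.profiles.items()}
        assert integrity_score(dists, self.profiles) == 10.0

    def test_atomized_pool_scores_one(self):
        dists = {name: fragment_distribution(p.length, p.length * 8.0, 0, 200)
                 for name, p in self.profiles.items()}
        assert integrity_score(dists, self.profiles) == pytest.approx(1.0, abs=0.2)

    def test_monotone_decreasing_in_cut_density(self):
        scores = []
        for density in (0.0, 1e-4, 1e-3, 1e-2):
            dists = {
                name: fragment_distribution(
                    p.length, p.susceptibility * density * (p.length - 1),
                    11, 50_000)
                for name, p in self.profiles.items()}
            scores.append(integrity_score(dists, self.profiles))
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_analytic_expectation_matches_mc(self):
        profiles = default_species("postmortem")
        density = 3e-4
        dists = {
            p.name: fragment_distribution(
                p.length, p.susceptibility * density * (p.length - 1), 5, 200_000)
            for p in profiles}
        mc = integrity_score(dists, {p.name: p for p in profiles})
        assert mc == pytest.approx(expected_integrity(profiles, density), rel=0.02)


class TestMeasure:
    def test_zero_composition_zero_areas(self, table1, rng):
        profiles = {p.name: p for p in default_species()}
        recs, uv, truth = measure({p: 0.0 for p in profiles}, profiles, table1,
                                  NoiseModel.zero(), rng, "s")
        assert all(r.auc == 0 for r in recs if r.channel == "C12")
        assert all(v == 0 for v in truth.values())

    def test_noise_free_identity_through_ladder(self, table1, rng):
        """With zero noise, normalize_sample recovers true concentrations up
        to one constant per modification branch."""
        profiles = {p.name: p for p in default_species()}
        masses = {"tRNA": 0.09, "mito_tRNA": 0.02, "rRNA18S": 1e-4,
                  "rRNA28S": 2e-4, "mRNA": 1e-5}
        recs, uv, truth = measure(masses, profiles, table1, NoiseModel.zero(),
                                  rng, "s", fraction="tRNA")
        col = quantify.normalize_sample(
            iodata.PeakTable(recs), uv, table1, quantify.ISTDSpec(), "s")
        noise = NoiseModel.zero()
        expected_const = noise.ms_gain / noise.istd_level / (noise.uv_gain / 4)
        for mod, conc in truth.items():
            if conc > 0:
                assert col[mod] / conc == pytest.approx(expected_const, rel=1e-9)

    def test_replicate_cv_within_twice_configured_sd(self, table1):
        profiles = {p.name: p for p in default_species()}
        masses = {"tRNA": 0.09, "mito_tRNA": 0.02, "rRNA18S": 1e-4,
                  "rRNA28S": 2e-4, "mRNA": 1e-5}
        noise = NoiseModel()
        rng = np.random.default_rng(5)
        cols = []
        for i in range(12):
            recs, uv, _ = measure(masses, profiles, table1, noise, rng, f"s{i}")
            cols.append(quantify.normalize_sample(
                iodata.PeakTable(recs), uv, table1, quantify.ISTDSpec(), f"s{i}"))
        values = np.vstack([c.to_numpy() for c in cols])
        present = values.mean(axis=0) > 0
        cv = values[:, present].std(axis=0) / values[:, present].mean(axis=0)
        total_sd = np.sqrt(noise.peak_area_sd**2 + noise.c13_sd**2 + noise.uv_sd**2)
        assert cv.max() < 2 * total_sd

    def test_chromatogram_mode_integrates_back(self, table1, rng):
        tr = table1.get("Am", "C12")
        chrom = synthesize_chromatogram(tr.ret_time, auc=250.0, rng=rng,
                                        noise_sd=1.0)
        auc, snr = quantify.integrate_peak(chrom, tr.ret_time, tr.ret_window)
        assert auc == pytest.approx(250.0, rel=0.05)
        assert snr > 5


class TestStudy:
    def test_determinism_byte_identical(self, tmp_path, table1):
        cfg = dataclasses.replace(default_config("braintissues", seed=7),
                                  replicates=2)
        for sub in ("a", "b"):
            simulate_study(cfg, table=table1, out_dir=tmp_path / sub)
        for name in ("peaks.csv", "uv_areas.csv", "samples.csv",
                     "ground_truth.json"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name

    def test_ground_truth_consistent_with_peaks(self, postmortem_sim):
        """Emitted light-channel areas sit around gain x true concentration
        within the declared noise."""
        noise = postmortem_sim.config.noise
        devs = []
        for rec in postmortem_sim.peaks.records:
            if rec.channel != "C12":
                continue
            truth = postmortem_sim.ground_truth[rec.sample_id]
            conc = truth["true_concentration"][rec.compound]
            if truth["fraction"] != "tRNA" or conc <= 0:
                continue
            devs.append(np.log(rec.auc / (noise.ms_gain * conc)))
        sd_total = np.sqrt(noise.peak_area_sd**2 + noise.injection_sd**2)
        assert abs(np.mean(devs)) < 0.05
        assert np.std(devs) < 2 * sd_total

    def test_liver_marker_truth_nondecreasing(self, postmortem_sim):
        truth = postmortem_sim.ground_truth
        means = []
        for t in (0.0, 1.0, 8.0, 24.0):
            vals = [v["true_concentration"]["m6,6A"] for v in truth.values()
                    if v["tissue"] == "liver" and v["frozen"]
                    and v["fraction"] == "tRNA" and v["time_h"] == t]
            means.append(np.mean(vals))
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_trna_marker_dilution_in_trna_window(self, postmortem_sim):
        """tRNA-core concentrations fall while rRNA share rises (liver)."""
        truth = postmortem_sim.ground_truth
        core_means, rrna_share = [], []
        for t in (0.0, 1.0, 8.0, 24.0):
            recs = [v for v in truth.values()
                    if v["tissue"] == "liver" and v["frozen"]
                    and v["fraction"] == "tRNA" and v["time_h"] == t]
            core_means.append(np.mean([r["true_concentration"]["m5C"] for r in recs]))
            shares = [(r["window_masses"]["rRNA18S"] + r["window_masses"]["rRNA28S"])
                      / sum(r["window_masses"].values()) for r in recs]
            rrna_share.append(np.mean(shares))
        assert all(a > b for a, b in zip(core_means, core_means[1:]))
        assert all(a < b for a, b in zip(rrna_share, rrna_share[1:]))

    def test_liver_degrades_faster_than_brain(self, postmortem_sim):
        truth = postmortem_sim.ground_truth

        def score(tissue, t):
            return np.mean([v["integrity"] for v in truth.values()
                            if v["tissue"] == tissue and v["frozen"]
                            and v["fraction"] == "tRNA" and v["time_h"] == t])

        assert score("liver", 1.0) < score("brain", 1.0)
        assert score("brain", 24.0) > 7.0  # brain stays near-intact

    def test_rf_rise_then_fall_of_trna_core(self, table1):
        """On a dense in-vitro grid the tRNA-derived RF mass has an interior
        maximum (analytic expectation; the fragments first accumulate in the
        window and are then cut below it)."""
        profiles = default_species("invitro")
        trna = next(p for p in profiles if p.name == "tRNA")
        rate, baseline = 0.2, 5e-5
        times = np.linspace(0, 3.0, 31)
        masses = [trna.mass_fraction * expected_mass_in_window(
            trna.length, trna.susceptibility * (baseline + rate * t), 15, 50)
            for t in times]
        peak = int(np.argmax(masses))
        assert 0 < peak < len(times) - 1
        assert masses[peak] > masses[0] and masses[peak] > 1.1 * masses[-1]

    def test_rate_recovery_within_20_percent(self, postmortem_sim):
        truth = postmortem_sim.ground_truth
        times, scores = [], []
        for t in (0.0, 1.0, 8.0, 24.0):
            vals = [v["integrity"] for v in truth.values()
                    if v["tissue"] == "liver" and v["frozen"]
                    and v["fraction"] == "tRNA" and v["time_h"] == t]
            times.append(t)
            scores.append(np.mean(vals))
        profiles = postmortem_sim.config.species_for("liver")
        r_hat = fit_cleavage_rate(times, scores, profiles,
                                  baseline_cut_density=5e-5,
                                  extra_cut_density=2e-5)
        assert r_hat == pytest.approx(7e-5, rel=0.20)


class TestConfig:
    def test_scenarios_available(self):
        for scenario in sd.SCENARIOS:
            cfg = default_config(scenario, seed=0)
            assert cfg.windows == DEFAULT_WINDOWS

    def test_postmortem_defaults_match_design(self):
        cfg = default_config("postmortem")
        assert cfg.timepoints == (0.0, 1.0, 8.0, 24.0)
        assert cfg.tissues["liver"] > cfg.tissues["brain"]
        assert cfg.windows["tRNA"] == (60, 75)
        assert cfg.windows["RF"] == (15, 50)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            dataclasses.replace(default_config("postmortem"),
                                windows={"a": (10, 40), "b": (30, 60)})

    def test_species_invariants(self):
        for p in default_species("postmortem"):
            if p.name in ("tRNA", "mito_tRNA"):
                assert p.mod_density.get("Am", 0) == 0
                assert p.mod_density.get("m6,6A", 0) == 0
        fractions = sum(p.mass_fraction for p in default_species())
        assert fractions == pytest.approx(1.0)
        rrna = sum(p.mass_fraction for p in default_species()
                   if p.name.startswith("rRNA"))
        assert rrna > 0.8

    def test_unknown_scenario(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            default_config("nope")
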