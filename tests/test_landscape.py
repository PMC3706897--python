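"""CNV landscape summaries: spectrum, rates, windows, recombination, exons."""

import math

import numpy as np
import pandas as pd
import pytest

from cghcnv import landscape as ls
from cghcnv.calling import DOWN, UP


def _calls(rows):
    return pd.DataFrame(rows, columns=["fragment_id", "genotype", "class"]).assign(
        log2=-2.0, posterior=0.99
    )


def _positions(n, chromosome="1H", spacing=700):
    return pd.DataFrame(
        {
            "fragment_id": [f"{chromosome}_f{i}" for i in range(n)],
            "chromosome": chromosome,
            "phys_start": np.arange(n) * spacing,
        }
    )


class TestFrequencySpectrum:
    def test_all_singletons(self):
        calls = _calls([(f"f{i}", "g1", DOWN) for i in range(5)])
        spec = ls.frequency_spectrum(calls, n_genotypes=3)
        assert spec.iloc[0].fraction == 1.0
        assert ls.singleton_fraction(calls) == 1.0

    def test_fully_shared_variant_tops_spectrum(self):
        calls = _calls([("f0", f"g{i}", DOWN) for i in range(4)])
        spec = ls.frequency_spectrum(calls, n_genotypes=4)
        assert spec.iloc[3].n_variants == 1
        assert spec.iloc[:3].n_variants.sum() == 0

    def test_spectrum_sums_to_total_variants(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(60):
            for gen in rng.choice(6, size=rng.integers(1, 6), replace=False):
                rows.append((f"f{i}", f"g{gen}", DOWN))
        calls = _calls(rows)
        spec = ls.frequency_spectrum(calls, n_genotypes=6)
        assert spec["n_variants"].sum() == calls["fragment_id"].nunique()

    def test_configured_singleton_fraction_recovered(self):
        rng = np.random.default_rng(1)
        rows = []
        target = 0.39
        n = 400
        for i in range(n):
            if rng.random() < target:
                rows.append((f"f{i}", "g0", DOWN))
            else:
                for gen in rng.choice(5, size=rng.integers(2, 5), replace=False):
                    rows.append((f"f{i}", f"g{gen}", DOWN))
        frac = ls.singleton_fraction(_calls(rows))
        assert abs(frac - target) <= 3 * math.sqrt(target * (1 - target) / n)


class TestWindows:
    def test_fully_variant_window(self):
        pos = _positions(20)
        calls = _calls([(f"1H_f{i}", "g1", DOWN) for i in range(20)])
        wins = ls.window_proportions(calls, pos, window_bp=20_000)
        assert wins.iloc[0].proportion == 1.0

    def test_boundary_fragment_assigned_by_start(self):
        pos = pd.DataFrame(
            {"fragment_id": ["a", "b"], "chromosome": "1H", "phys_start": [999, 1000]}
        )
        calls = _calls([("a", "g", DOWN), ("b", "g", DOWN)])
        wins = ls.window_proportions(calls, pos, window_bp=1000, chrom_lengths={"1H": 2000})
        assert wins.iloc[0].n_fragments == 1  # [0, 1000)
        assert wins.iloc[1].n_fragments == 1  # [1000, 2000)

    def test_empty_window_null_proportion(self):
        pos = _positions(5, spacing=100)
        wins = ls.window_proportions(
            _calls([]), pos, window_bp=1000, chrom_lengths={"1H": 5000}
        )
        assert np.isnan(wins.iloc[3].proportion)

    def test_telomere_weighted_variants_enrich_end_windows(self):
        rng = np.random.default_rng(2)
        pos = _positions(600, spacing=1000)  # 0.6 Mb chromosome
        length = 600_000
        rows = []
        for row in pos.itertuples(index=False):
            x = row.phys_start / length
            p = 0.05 + 0.4 * (2 * abs(x - 0.5)) ** 2
            if rng.random() < p:
                rows.append((row.fragment_id, "g", DOWN))
        wins = ls.window_proportions(
            _calls(rows), pos, window_bp=100_000, chrom_lengths={"1H": length}
        )
        props = wins["proportion"].to_numpy()
        ends = np.nanmean([props[0], props[-1]])
        mids = np.nanmean(props[2:4])
        assert ends > mids

    def test_chromosome_proportion_is_weighted_window_mean(self):
        rng = np.random.default_rng(3)
        pos = _positions(200, spacing=997)
        rows = [
            (f"1H_f{i}", "g", DOWN) for i in range(200) if rng.random() < 0.2
        ]
        calls = _calls(rows)
        wins = ls.window_proportions(calls, pos, window_bp=20_000).dropna()
        rates = ls.chromosome_rates(calls, pos, window_bp=20_000)
        weighted = (wins["proportion"] * wins["n_fragments"]).sum() / wins["n_fragments"].sum()
        assert rates.iloc[0].proportion == pytest.approx(weighted)


def _panel(rng, rates_by_chrom, windows=25, frags_per_window=30, window_bp=100_000):
    """Binomial per-window variant construction over 7 chromosomes."""
    pos_frames, call_rows = [], []
    for chrom, rate in rates_by_chrom.items():
        ids = []
        starts = []
        for w in range(windows):
            for j in range(frags_per_window):
                ids.append(f"{chrom}_w{w}_f{j}")
                starts.append(w * window_bp + j * (window_bp // frags_per_window))
        pos_frames.append(
            pd.DataFrame({"fragment_id": ids, "chromosome": chrom, "phys_start": starts})
        )
        for fid in ids:
            if rng.random() < rate:
                call_rows.append((fid, "g", DOWN))
    return pd.concat(pos_frames, ignore_index=True), _calls(call_rows)


class TestChromosomeRates:
    def test_false_positive_rate_near_alpha_under_equal_rates(self):
        chroms = [f"{i}H" for i in range(1, 8)]
        n_sig = 0
        n_tests = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            pos, calls = _panel(rng, {c: 0.15 for c in chroms})
            rates = ls.chromosome_rates(calls, pos, window_bp=100_000)
            n_sig += int((rates["t_test_p"] < 0.05).sum())
            n_tests += len(rates)
        assert n_sig <= 0.10 * n_tests

    def test_half_rate_chromosome_detected(self):
        chroms = {f"{i}H": 0.15 for i in range(1, 8)}
        chroms["4H"] = 0.075
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            pos, calls = _panel(rng, chroms)
            rates = ls.chromosome_rates(calls, pos, window_bp=100_000).set_index("chromosome")
            if rates.loc["4H", "t_test_p"] < 0.05:
                hits += 1
        assert hits >= 9

    def test_zero_variants_zero_proportions(self):
        rng = np.random.default_rng(4)
        pos, _ = _panel(rng, {"1H": 0.0, "2H": 0.0})
        rates = ls.chromosome_rates(_calls([]), pos, window_bp=100_000)
        assert (rates["proportion"] == 0).all()


class TestGroupDifference:
    def test_wild_only_variants_all_positive(self):
        pos = _positions(50)
        calls = _calls([(f"1H_f{i}", "w1", DOWN) for i in range(0, 50, 3)])
        groups = {"w1": "wild", "c1": "cultivated"}
        diff = ls.group_difference_profile(calls, pos, groups, window_bp=10_000)
        assert diff.attrs["n_negative"] == 0
        assert diff.attrs["n_positive"] > 0
        assert (diff["difference"] >= 0).all()

    def test_two_to_one_rates_skew_positive(self):
        rng = np.random.default_rng(5)
        pos = _positions(400)
        rows = []
        for row in pos.itertuples(index=False):
            if rng.random() < 0.30:
                rows.append((row.fragment_id, "w1", DOWN))
            if rng.random() < 0.15:
                rows.append((row.fragment_id, "c1", DOWN))
        groups = {"w1": "wild", "c1": "cultivated"}
        diff = ls.group_difference_profile(_calls(rows), pos, groups, window_bp=20_000)
        assert diff.attrs["n_positive"] > diff.attrs["n_negative"]

    def test_equal_rates_mean_difference_near_zero(self):
        rng = np.random.default_rng(6)
        pos = _positions(400)
        rows = []
        for row in pos.itertuples(index=False):
            for geno in ("w1", "c1"):
                if rng.random() < 0.2:
                    rows.append((row.fragment_id, geno, DOWN))
        groups = {"w1": "wild", "c1": "cultivated"}
        diff = ls.group_difference_profile(_calls(rows), pos, groups, window_bp=20_000)
        assert abs(diff["difference"].mean()) < 1.0

    def test_unlabeled_genotype_rejected(self):
        pos = _positions(5)
        calls = _calls([("1H_f0", "mystery", DOWN)])
        with pytest.raises(ValueError):
            ls.group_difference_profile(calls, pos, {"w1": "wild", "c1": "cultivated"})


def _map_for_bins(densities, bin_bp=10_000_000, chromosome="1H"):
    """Genetic map whose cM/Mb over bin i equals densities[i]."""
    edges = np.arange(len(densities) + 1) * bin_bp
    cm = np.concatenate([[0.0], np.cumsum(np.asarray(densities) * bin_bp / 1e6)])
    return pd.DataFrame({"chromosome": chromosome, "bp": edges, "cM": cm})


def _binned_positions(n_bins, frags_per_bin=40, bin_bp=10_000_000, chromosome="1H"):
    ids, starts = [], []
    for b in range(n_bins):
        for j in range(frags_per_bin):
            ids.append(f"{chromosome}_b{b}_f{j}")
            starts.append(b * bin_bp + j * (bin_bp // frags_per_bin))
    return pd.DataFrame(
        {"fragment_id": ids, "chromosome": chromosome, "phys_start": starts}
    )


class TestRecombinationCorrelation:
    def test_monotone_relationship_gives_rho_one(self):
        dens = np.linspace(0.5, 3.0, 6)
        gmap = _map_for_bins(dens)
        pos = _binned_positions(6)
        rows = []
        for b in range(6):
            for j in range(5 + 5 * b):  # strictly increasing variant count
                rows.append((f"1H_b{b}_f{j}", "g", DOWN))
        rho, _p, table = ls.recombination_cnv_correlation(_calls(rows), pos, gmap)
        assert rho == pytest.approx(1.0)
        assert len(table) == 6

    def test_independent_placement_low_rho(self):
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            dens = rng.uniform(0.2, 3.0, 50)
            gmap = _map_for_bins(dens)
            pos = _binned_positions(50)
            rows = [
                (fid, "g", DOWN) for fid in pos["fragment_id"] if rng.random() < 0.2
            ]
            rho, _p, _t = ls.recombination_cnv_correlation(_calls(rows), pos, gmap)
            if abs(rho) < 0.3:
                ok += 1
        assert ok >= 9

    def test_density_proportional_placement_recovers_positive_rho(self):
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(400 + seed)
            dens = rng.uniform(0.2, 3.0, 50)
            gmap = _map_for_bins(dens)
            pos = _binned_positions(50, frags_per_bin=80)
            rows = []
            for b in range(50):
                p = 0.02 + 0.15 * dens[b] / 3.0
                for j in range(80):
                    if rng.random() < p:
                        rows.append((f"1H_b{b}_f{j}", "g", DOWN))
            rho, _p, _t = ls.recombination_cnv_correlation(_calls(rows), pos, gmap)
            if rho > 0.4:
                ok += 1
        assert ok >= 9

    def test_too_few_bins_signaled(self):
        gmap = _map_for_bins([1.0, 2.0])
        pos = _binned_positions(2)
        with pytest.raises(ValueError):
            ls.recombination_cnv_correlation(_calls([]), pos, gmap)


class TestExonOverlap:
    def _frags(self, n):
        return pd.DataFrame(
            {
                "fragment_id": [f"f{i}" for i in range(n)],
                "contig": "c",
                "start": np.arange(n) * 700,
                "end": np.arange(n) * 700 + 200,
            }
        )

    def test_whole_genome_annotation(self):
        frags = self._frags(10)
        ann = pd.DataFrame([{"contig": "c", "start": 0, "end": 10_000}])
        calls = _calls([("f0", "g", UP), ("f1", "g", DOWN)])
        out = ls.exon_overlap_summary(calls, frags, ann)
        assert out[UP] == 1.0 and out[DOWN] == 1.0

    def test_empty_annotation_warns_zero(self):
        frags = self._frags(5)
        calls = _calls([("f0", "g", UP)])
        with pytest.warns(UserWarning):
            out = ls.exon_overlap_summary(calls, frags, pd.DataFrame(columns=["contig", "start", "end"]))
        assert out[UP] == 0.0

    def test_thirty_percent_on_exons_recovered(self):
        rng = np.random.default_rng(7)
        n = 600
        frags = self._frags(n)
        exonic = rng.random(n) < 0.30
        ann = pd.DataFrame(
            [
                {"contig": "c", "start": i * 700 + 50, "end": i * 700 + 150}
                for i in range(n)
                if exonic[i]
            ]
        )
        calls = _calls([(f"f{i}", "g", DOWN) for i in range(n)])
        out = ls.exon_overlap_summary(calls, frags, ann)
        se = math.sqrt(0.3 * 0.7 / n)
        assert abs(out[DOWN] - exonic.mean()) < 1e-12
        assert abs(out[DOWN] - 0.30) <= 3 * se
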