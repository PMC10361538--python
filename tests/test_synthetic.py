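import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import tilmotif as tm
from tilmotif.motifs import find_motif_offsets
from tilmotif.synthetic import CohortManifest, audit_cohort, score_expansion


def fit_zipf_slope(counts):
    """log-log rank-frequency slope over well-sampled ranks (count >= 5)."""
    c = np.sort(np.asarray(counts, float))[::-1]
    c = c[c >= 5]
    ranks = np.arange(1, len(c) + 1)
    slope, *_ = sps.linregress(np.log(ranks), np.log(c / c.sum()))
    return slope


class TestRepertoireGeneration:
    def test_deterministic_given_seed(self, default_config):
        a = tm.generate_repertoire(default_config, "tumor", "p1", seed=5)
        b = tm.generate_repertoire(default_config, "tumor", "p1", seed=5)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_zipf_slope_recovered(self):
        cfg = tm.GeneratorConfig(
            zipf_exponents={"other": 1.1}, clones_per_sample=1000,
            reads_per_sample=200_000)
        t = tm.generate_repertoire(cfg, "other", "p1", seed=2)
        slope = fit_zipf_slope(t.df["count"])
        assert abs(slope + 1.1) < 0.15

    def test_exclusive_motifs_absent_from_comparators(self, cohort):
        """Exclusive motifs are never planted outside tumor; chance carriage
        at the manifest offset stays at background level."""
        exclusive = [m for m in cohort.manifest.planted_motifs if m.kind == "exclusive"]
        for tables, is_tumor in ((cohort.tumor, True), (cohort.healthy, False)):
            per_sample = []
            for t in tables:
                n = sum(
                    pm.offset in find_motif_offsets(aa, pm.motif)
                    for pm in exclusive for aa in t.df["cdr3_aa"]
                )
                per_sample.append(n)
            if is_tumor:
                assert np.mean(per_sample) >= 5 * len(exclusive)
            else:
                assert np.mean(per_sample) <= 1.0

    def test_generated_tables_pass_io_validation(self, tmp_path, default_config):
        """Every generated AIRR file re-reads with zero dropped rows."""
        cfg = tm.GeneratorConfig(n_tumor=2, n_healthy=1, n_pb=1, n_til_pairs=1)
        cohort = tm.generate_cohort(cfg, seed=4)
        tm.write_cohort(cohort, tmp_path, dialect="airr")
        for t in cohort.all_tables():
            back, log = tm.read_clonotype_table(tmp_path / f"{t.sample_id}.tsv",
                                                dialect="airr")
            assert log.dropped == {}
            assert back.total_reads == t.total_reads

    def test_cohort_round_trip(self, tmp_path):
        cfg = tm.GeneratorConfig(n_tumor=2, n_healthy=1, n_pb=1, n_til_pairs=1)
        cohort = tm.generate_cohort(cfg, seed=4)
        tm.write_cohort(cohort, tmp_path)
        back = tm.read_cohort(tmp_path)
        assert len(back.tumor) == 2 and len(back.til_pairs) == 1
        assert back.manifest.control_sets.keys() == cohort.manifest.control_sets.keys()
        assert [m.motif for m in back.manifest.planted_motifs] == \
               [m.motif for m in cohort.manifest.planted_motifs]


class TestManifest:
    def test_audit_passes_on_default_cohort(self, cohort):
        audit = audit_cohort(cohort)
        assert audit["planted_motifs_discoverable"]
        assert audit["viral_spikes_exact"]

    def test_json_round_trip(self, cohort):
        back = CohortManifest.from_json(cohort.manifest.to_json())
        assert [m.motif for m in back.planted_motifs] == \
               [m.motif for m in cohort.manifest.planted_motifs]
        assert len(back.true_expansions) == len(cohort.manifest.true_expansions)


class TestPairedTil:
    def test_degenerate_fold_gives_empty_truth(self, default_config):
        """A fold-change distribution degenerate at 1 plants no real
        expansions, so the truth list is empty."""
        import dataclasses

        cfg = dataclasses.replace(default_config, expansion_fold_range=(1.0, 1.0))
        _, _, truths = tm.generate_paired_til(cfg, "p1", seed=1)
        assert truths == []

    def test_truth_satisfies_expansion_definition(self, default_config):
        """Every truth entry has fold >= 10 and max frequency >= 0.1%."""
        _, _, truths = tm.generate_paired_til(default_config, "p1", seed=3)
        assert len(truths) == 2 * default_config.n_expanded_per_direction
        for e in truths:
            assert e.fold >= 10
            assert max(e.pre_freq, e.rep_freq) >= 0.001
            hi, lo = ((e.pre_freq, e.rep_freq) if e.expanded_in == "pre"
                      else (e.rep_freq, e.pre_freq))
            assert hi / lo == pytest.approx(e.fold)

    def test_designated_mass_balanced(self, default_config):
        """Designated clones carry equal total true frequency in both
        samples, so non-designated clones keep identical frequencies."""
        _, _, truths = tm.generate_paired_til(default_config, "p1", seed=6)
        assert sum(e.pre_freq for e in truths) == pytest.approx(
            sum(e.rep_freq for e in truths))

    def test_forced_expansion_recovered(self, default_config):
        """A designated clone at ~5% pre vs ~0.2% rep is called expanded in
        pre by the downstream test."""
        pre, rep, truths = tm.generate_paired_til(default_config, "p1", seed=8)
        res = tm.test_expansion(pre, rep, mode="aa")
        s = score_expansion(
            CohortManifest(true_expansions=truths), "p1", res)
        assert s["fn"] == 0

    def test_power_matches_monte_carlo_oracle(self, default_config):
        """Empirical detection power over simulated pairs agrees with a
        direct Monte-Carlo oracle drawing the same 2x2 tables."""
        rng = np.random.default_rng(12)
        n_pairs = 60
        detected = total = 0
        truth_freqs = []
        for i in range(n_pairs):
            pre, rep, truths = tm.generate_paired_til(
                default_config, f"p{i}", int(rng.integers(2**31)))
            res = tm.test_expansion(pre, rep, mode="aa")
            called = set(res.loc[res["expanded_in"] != "none", "clonotype"])
            for e in truths:
                total += 1
                detected += e.cdr3_aa in called
                truth_freqs.append((e.pre_freq, e.rep_freq))
        power = detected / total
        # oracle: same per-clone 2x2 sampling, plain Fisher at alpha
        n = default_config.reads_per_sample
        hits = 0
        for f_pre, f_rep in truth_freqs:
            a = rng.binomial(n, f_pre)
            b = rng.binomial(n, f_rep)
            p = sps.fisher_exact([[a, n - a], [b, n - b]])[1]
            hits += p < 0.05
        oracle_power = hits / len(truth_freqs)
        assert abs(power - oracle_power) <= 0.05


class TestCellTable:
    def test_deterministic(self, default_config):
        a_cells, a_expr, _ = tm.generate_cell_table(default_config, seed=9)
        b_cells, b_expr, _ = tm.generate_cell_table(default_config, seed=9)
        pd.testing.assert_frame_equal(a_cells, b_cells)
        pd.testing.assert_frame_equal(a_expr, b_expr)

    def test_biased_carriage_drives_dominant_call(self, cell_data):
        """A motif assigned 90% to one phenotype yields that dominant call."""
        from tilmotif.motifs import MotifRecord

        cells, _, manifest = cell_data
        pm = manifest.planted_motifs[0]
        rec = MotifRecord(pm.motif, frozenset([pm.offset]), frozenset(), 0, 0,
                          "tumor", 0, 0, 1.0, 0.0, 0.0)
        calls = tm.assign_motif_phenotypes(cells, [rec])
        assert calls and calls[0].dominant_phenotype == pm.target_phenotype
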