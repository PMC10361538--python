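import numpy as np
import pytest
from scipy import stats as sps

import tilmotif as tm
from tilmotif.motifs import MotifIndex, MotifRecord
from tilmotif.stats import rank_sum_test

from conftest import make_table


def record(motif, offsets=(4,)):
    return MotifRecord(motif=motif, offsets=frozenset(offsets), cluster=frozenset(),
                       cluster_size=3, n_samples=1, discovery_tissue="tumor",
                       count_cohort=3, count_reference=0, fold=10.0,
                       enrichment_p=1e-4, p_adjusted=1e-3)


def index_of(*motifs):
    return MotifIndex(records={r.motif: r for r in motifs}, tissue="tumor")


def carrier_table(freqs_with_motif, motif="QWER", offset=4, total=10_000,
                  sample_id="s", tissue="tumor"):
    """Table where given frequencies belong to motif carriers at ``offset``."""
    aa, counts = [], []
    for i, f in enumerate(freqs_with_motif):
        base = f"CASS{'ADEFGHIKLM'[i % 10] * 9}QYF"
        aa.append(base[:offset] + motif + base[offset + len(motif):])
        counts.append(int(round(f * total)))
    filler = total - sum(counts)
    if filler > 0:
        aa.append("CASSYYYYYYYYYYQYF")
        counts.append(filler)
    return make_table(counts, aa=aa, v=[f"TRBV{i}" for i in range(len(aa))],
                      sample_id=sample_id, tissue=tissue)


class TestPooledFrequency:
    def test_absent_motif_is_zero(self):
        t = carrier_table([0.01], motif="QWER")
        assert tm.pooled_motif_frequency(t, record("WXYZ")) == 0.0

    def test_carriers_sum(self):
        t = carrier_table([0.01, 0.02], motif="QWER")
        assert tm.pooled_motif_frequency(t, record("QWER")) == pytest.approx(0.03)

    def test_disallowed_offset_is_zero(self):
        t = carrier_table([0.01], motif="QWER", offset=4)
        assert tm.pooled_motif_frequency(t, record("QWER", offsets=(6,))) == 0.0

    def test_unique_weighting(self):
        t = carrier_table([0.01, 0.02], motif="QWER")  # 2 carriers of 3 clones
        assert tm.pooled_motif_frequency(t, record("QWER"), weighting="unique") \
            == pytest.approx(2 / 3)


class TestClassification:
    def _samples(self, tumor_f, comp_f, motif="QWER"):
        tumor = [carrier_table([f], motif=motif, sample_id=f"t{i}")
                 if f > 0 else carrier_table([0.0], motif="ZZZZ", sample_id=f"t{i}")
                 for i, f in enumerate(tumor_f)]
        comp = [carrier_table([f], motif=motif, sample_id=f"h{i}", tissue="healthy_kidney")
                if f > 0 else carrier_table([0.0], motif="ZZZZ", sample_id=f"h{i}",
                                            tissue="healthy_kidney")
                for i, f in enumerate(comp_f)]
        return tumor, comp

    def test_tumor_only_motif_is_exclusive(self):
        tumor, comp = self._samples([0.02] * 3, [0.0] * 3)
        assoc = tm.classify_motifs(index_of(record("QWER")), {"healthy_kidney": index_of()},
                                   tumor, {"healthy_kidney": comp})
        assert assoc[0].status == "exclusive"

    def test_shared_enriched_motif(self):
        """10x tumor frequencies across 8 vs 8 samples: significant rank-sum,
        log2fc > 1, status enriched."""
        tumor, comp = self._samples([0.05] * 8, [0.005] * 8)
        idx = index_of(record("QWER"))
        assoc = tm.classify_motifs(idx, {"healthy_kidney": idx}, tumor,
                                   {"healthy_kidney": comp})
        a = assoc[0]
        assert a.status == "enriched"
        assert a.log2fc["healthy_kidney"] > 1

    def test_wilcoxon_matches_exact_permutation_oracle(self):
        """Zero-inflated pooled frequencies, n <= 10 per group: the p-value
        equals scipy's full permutation enumeration."""
        rng = np.random.default_rng(5)
        x = np.where(rng.random(8) < 0.4, 0.0, rng.uniform(0.01, 0.05, 8))
        y = np.where(rng.random(8) < 0.8, 0.0, rng.uniform(0.001, 0.01, 8))

        def stat(a, b):
            ranks = sps.rankdata(np.concatenate([a, b]))
            return ranks[: len(a)].sum()

        ref = sps.permutation_test((x, y), stat, permutation_type="independent",
                                   alternative="two-sided", n_resamples=np.inf)
        assert rank_sum_test(x, y) == pytest.approx(ref.pvalue, abs=1e-9)

    def test_degenerate_all_zero_rejected(self):
        tumor, comp = self._samples([0.0] * 3, [0.0] * 3)
        idx = index_of(record("QWER"))
        assoc = tm.classify_motifs(idx, {"healthy_kidney": idx}, tumor,
                                   {"healthy_kidney": comp})
        assert assoc[0].status == "rejected"
        assert assoc[0].undefined_log2fc

    def test_empty_comparator_cohort_is_error(self):
        tumor, _ = self._samples([0.02], [])
        with pytest.raises(tm.RepertoireError, match="zero samples"):
            tm.classify_motifs(index_of(record("QWER")), {"healthy_kidney": index_of()},
                               tumor, {"healthy_kidney": []})

    def test_zero_inflation_monotonicity(self):
        """Adding comparator samples at frequency 0 can only strengthen a
        shared motif's enrichment signal."""
        tumor_f = [0.05] * 6
        comp_f = [0.01] * 6
        tumor, comp = self._samples(tumor_f, comp_f)
        idx = index_of(record("QWER"))
        base = tm.classify_motifs(idx, {"healthy_kidney": idx}, tumor,
                                  {"healthy_kidney": comp})[0]
        _, zeros = self._samples([], [0.0] * 4)
        more = tm.classify_motifs(idx, {"healthy_kidney": idx}, tumor,
                                  {"healthy_kidney": comp + zeros})[0]
        assert more.wilcoxon_p["healthy_kidney"] <= base.wilcoxon_p["healthy_kidney"] + 1e-12


class TestPruning:
    def _assoc(self):
        return [tm.MotifAssociation(motif=m, status="exclusive")
                for m in ("AAA", "BBB", "CCC")]

    def test_control_hit_pruned(self):
        out = tm.prune_against_controls(self._assoc(), [("viral", {"BBB"})])
        by = {a.motif: a for a in out}
        assert by["BBB"].status == "pruned" and by["BBB"].pruned_by == ["viral"]
        assert by["AAA"].status == "exclusive"

    def test_empty_controls_identity(self):
        out = tm.prune_against_controls(self._assoc(), [])
        assert [a.status for a in out] == ["exclusive"] * 3

    def test_order_independent_and_idempotent(self):
        sets = [("x", {"AAA"}), ("y", {"AAA", "CCC"})]
        a1 = tm.prune_against_controls(self._assoc(), sets)
        a2 = tm.prune_against_controls(self._assoc(), sets[::-1])
        assert [(a.motif, a.status, a.pruned_by) for a in a1] == \
               [(a.motif, a.status, a.pruned_by) for a in a2]
        a3 = tm.prune_against_controls(a1, sets)
        assert [(a.motif, a.status, a.pruned_by) for a in a3] == \
               [(a.motif, a.status, a.pruned_by) for a in a1]

    def test_partition_property(self, discovery_run):
        """Every tumor-discovered motif lands in exactly one status."""
        idx, assoc = discovery_run
        statuses = {a.motif: a.status for a in assoc}
        assert set(statuses) == set(idx["tumor"].motifs())
        assert set(statuses.values()) <= {"exclusive", "enriched", "rejected", "pruned"}

    def test_contaminants_pruned_exactly(self, cohort, discovery_run):
        _, assoc = discovery_run
        pruned = sorted(a.motif for a in assoc if a.status == "pruned")
        assert pruned == cohort.manifest.contaminant_motifs()
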