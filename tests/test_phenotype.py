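import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import tilmotif as tm
from tilmotif.motifs import MotifRecord
from tilmotif.phenotype import DEFAULT_MODULES
from tilmotif.synthetic import score_phenotypes


def record(motif, offsets=(4,)):
    return MotifRecord(motif=motif, offsets=frozenset(offsets), cluster=frozenset(),
                       cluster_size=3, n_samples=1, discovery_tissue="tumor",
                       count_cohort=3, count_reference=0, fold=10.0,
                       enrichment_p=1e-4, p_adjusted=1e-3)


def cell_frame(carrier_phenos, background_phenos, motif="QWER", offset=4):
    """Cells whose CDR3 carries ``motif`` get the first phenotype list."""
    rows = []
    for i, p in enumerate(carrier_phenos):
        aa = "CASSAAAAAAAAAQYF"
        rows.append({"cell_id": f"c{i:04d}",
                     "cdr3_aa": aa[:offset] + motif + aa[offset + len(motif):],
                     "phenotype": p})
    for j, p in enumerate(background_phenos):
        rows.append({"cell_id": f"b{j:04d}", "cdr3_aa": "CASSYYYYYYYYYQYF",
                     "phenotype": p})
    return pd.DataFrame(rows)


class TestAssignment:
    def test_forced_dominance(self):
        """9/10 supporting cells of phenotype P, P rare elsewhere."""
        bg = ["P"] * 10 + ["Q"] * 45 + ["R"] * 45
        cells = cell_frame(["P"] * 9 + ["Q"], bg)
        calls = tm.assign_motif_phenotypes(cells, [record("QWER")])
        assert len(calls) == 1
        assert calls[0].dominant_phenotype == "P"
        assert calls[0].n_supporting_cells == 10

    def test_below_min_cells_no_call(self):
        cells = cell_frame(["P"] * 4, ["Q"] * 50)
        assert tm.assign_motif_phenotypes(cells, [record("QWER")]) == []

    def test_missing_phenotype_is_error(self):
        cells = cell_frame(["P"] * 6, ["Q"] * 10)
        cells.loc[0, "phenotype"] = ""
        with pytest.raises(tm.RepertoireError, match="phenotype"):
            tm.assign_motif_phenotypes(cells, [record("QWER")])

    def test_duplicate_cell_id_is_error(self):
        cells = cell_frame(["P"] * 6, ["Q"] * 10)
        cells.loc[1, "cell_id"] = cells.loc[0, "cell_id"]
        with pytest.raises(tm.RepertoireError, match="cell_id"):
            tm.assign_motif_phenotypes(cells, [record("QWER")])

    def test_or_symmetry_under_relabeling(self):
        cells = cell_frame(["P"] * 6 + ["Q"] * 2, ["P"] * 20 + ["Q"] * 30 + ["R"] * 10)
        base = tm.assign_motif_phenotypes(cells, [record("QWER")])[0]
        swap = {"P": "Q", "Q": "P", "R": "R"}
        relabeled = cells.assign(phenotype=cells["phenotype"].map(swap))
        other = tm.assign_motif_phenotypes(relabeled, [record("QWER")])[0]
        for p, or_ in base.odds_ratios.items():
            assert other.odds_ratios[swap[p]] == pytest.approx(or_)

    def test_random_phenotypes_uniform_dominant_distribution(self):
        """With random labels the dominant call has no preferred phenotype
        (chi-square goodness of fit over replicates)."""
        rng = np.random.default_rng(3)
        labels = list("ABCD")
        counts = {p: 0 for p in labels}
        for _ in range(400):
            cells = cell_frame(rng.choice(labels, size=12),
                               rng.choice(labels, size=60))
            calls = tm.assign_motif_phenotypes(cells, [record("QWER")])
            counts[calls[0].dominant_phenotype] += 1
        chi = sps.chisquare(list(counts.values()))
        assert chi.pvalue > 0.001

    def test_end_to_end_recovery(self, cell_data):
        """Phenotype-biased motif carriage is recovered for nearly all
        well-supported motifs; no call ever has < 5 supporting cells."""
        cells, _, manifest = cell_data
        recs = [record(m.motif, offsets=(m.offset,)) for m in manifest.planted_motifs]
        calls = tm.assign_motif_phenotypes(cells, recs)
        assert all(c.n_supporting_cells >= 5 for c in calls)
        s = score_phenotypes(manifest, calls)
        assert s["n_scored"] >= 5
        assert s["concordance"] >= 0.95


class TestModuleScore:
    def _matrix(self, rng, n_cells=300, n_genes=120):
        genes = [f"G{i:03d}" for i in range(n_genes)]
        base = rng.lognormal(0, 1, size=n_genes)
        counts = rng.poisson(base, size=(n_cells, n_genes))
        return pd.DataFrame(counts.astype(float), columns=genes)

    def test_all_zero_matrix_scores_zero(self):
        expr = pd.DataFrame(np.zeros((50, 60)), columns=[f"G{i}" for i in range(60)])
        spec = tm.ModuleScoreSpec("m", ("G0", "G1"), n_bins=10)
        assert np.allclose(tm.module_score(expr, spec), 0.0)

    def test_uniform_shift_recovered(self, rng):
        """Module genes shifted by +delta over an exchangeable background:
        mean score recovers delta within 5%."""
        n_cells, n_genes, delta = 2000, 120, 1.5
        genes = [f"G{i:03d}" for i in range(n_genes)]
        expr = pd.DataFrame(rng.normal(1.0, 0.3, size=(n_cells, n_genes)),
                            columns=genes).clip(lower=0)
        module = tuple(rng.choice(genes, size=6, replace=False))
        expr[list(module)] += delta
        score = tm.module_score(expr, tm.ModuleScoreSpec("m", module, seed=1))
        assert abs(score.mean() - delta) < 0.05 * delta

    def test_random_gene_set_mean_near_zero(self, rng):
        expr = np.log1p(self._matrix(rng))
        genes = tuple(rng.choice(expr.columns, size=8, replace=False))
        score = tm.module_score(expr, tm.ModuleScoreSpec("m", genes, seed=2))
        se = score.std() / np.sqrt(len(score))
        assert abs(score.mean()) < 3 * se + 1e-9

    def test_deterministic_given_seed(self, rng):
        expr = np.log1p(self._matrix(rng))
        spec = tm.ModuleScoreSpec("m", tuple(expr.columns[:5]), seed=7)
        a = tm.module_score(expr, spec)
        b = tm.module_score(expr, spec)
        assert (a == b).all()

    def test_missing_genes_warn_and_drop(self, rng):
        expr = np.log1p(self._matrix(rng))
        spec = tm.ModuleScoreSpec("m", ("G000", "NOT_A_GENE"), seed=0)
        score = tm.module_score(expr, spec)
        assert len(score) == len(expr)
        with pytest.raises(tm.RepertoireError):
            tm.module_score(expr, tm.ModuleScoreSpec("m", ("NOPE",), seed=0))

    def test_signature_elevated_in_target_phenotype(self, cell_data):
        """The generated expression matrix elevates each signature in its
        owning phenotype."""
        cells, expr, _ = cell_data
        logn = tm.log_normalize(expr)
        targets = {"cytotoxicity": "CD4_cytotoxic", "exhaustion": "CD8_Tex",
                   "tissue_resident": "CD8_Trm"}
        phenos = cells.set_index("cell_id")["phenotype"]
        for spec in DEFAULT_MODULES:
            score = tm.module_score(logn, spec)
            own = score[(phenos == targets[spec.name]).to_numpy()]
            rest = score[(phenos != targets[spec.name]).to_numpy()]
            assert own.mean() > rest.mean() + 0.3

    def test_zero_effect_scores_indistinguishable(self):
        """With module_effect 0 the rank-sum p between target and other
        phenotypes is uniform across replicates (KS test)."""
        cfg = tm.GeneratorConfig(module_effect=0.0, n_cells=400, n_genes=120)
        pvals = []
        for seed in range(60):
            cells, expr, _ = tm.generate_cell_table(cfg, seed=seed)
            logn = tm.log_normalize(expr)
            score = tm.module_score(logn, tm.ModuleScoreSpec(
                "cytotoxicity", DEFAULT_MODULES[0].genes, seed=seed))
            mask = (cells["phenotype"] == "CD4_cytotoxic").to_numpy()
            if mask.sum() >= 5 and (~mask).sum() >= 5:
                pvals.append(sps.mannwhitneyu(score[mask], score[~mask])[1])
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001
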