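import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pgskit import (
    ClinicalTable,
    QpcrPanel,
    qpcr_to_expression,
    recode_validation_outcomes,
    score_samples,
    stratified_split,
)
from pgskit.survstats import fisher_exact_2x2


def clinical_from(**cols):
    n = len(next(iter(cols.values())))
    idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    return ClinicalTable(pd.DataFrame(cols, index=idx))


class TestRecoding:
    def test_relapse_mode(self):
        clin = clinical_from(relapse=["yes", "no", "yes"], dfs_event=[1, 0, 1])
        labels = recode_validation_outcomes(clin, "relapse")
        assert labels.tolist() == [1, 0, 1]

    def test_death_mode(self):
        clin = clinical_from(os_event=[0, 1, 0])
        labels = recode_validation_outcomes(clin, "death")
        assert labels.tolist() == [0, 1, 0]

    def test_missing_outcomes_excluded_and_counted(self, capsys):
        clin = clinical_from(os_event=[1.0, np.nan, 0.0, np.nan])
        labels = recode_validation_outcomes(clin, "death")
        assert len(labels) == 2
        assert "excluded 2" in capsys.readouterr().err

    def test_unknown_mode_rejected(self):
        clin = clinical_from(os_event=[1])
        with pytest.raises(ValueError):
            recode_validation_outcomes(clin, "remission")


class TestStratifiedSplit:
    def make_cohort(self, n=528, seed=0):
        rng = np.random.default_rng(seed)
        return clinical_from(
            age=rng.normal(60, 12, n),
            gender=rng.choice(["female", "male"], n),
        )

    def test_reference_cohort_sizes(self):
        """528 samples at fraction 0.75 split exactly 396 / 132."""
        clin = self.make_cohort()
        train, valid = stratified_split(clin, 0.75, seed=3)
        assert len(train) == 396 and len(valid) == 132
        assert set(train) | set(valid) == set(clin.sample_ids)
        assert not set(train) & set(valid)

    def test_balanced_strata_exact_halves(self):
        clin = clinical_from(
            age=np.tile([30.0, 40.0, 50.0, 60.0], 10),
            gender=np.tile(["female", "male"], 20),
        )
        train, valid = stratified_split(clin, 0.5, seed=1)
        assert len(train) == len(valid) == 20

    def test_seed_determinism(self):
        clin = self.make_cohort()
        assert stratified_split(clin, 0.75, seed=9) == stratified_split(clin, 0.75, seed=9)
        assert stratified_split(clin, 0.75, seed=9) != stratified_split(clin, 0.75, seed=10)

    def test_stratification_balance(self):
        """Across seeds, split membership is independent of the strata
        (chi-square on strata x split never significant at 0.01)."""
        clin = self.make_cohort(n=400, seed=4)
        df = clin.data
        bins = pd.qcut(df["age"], 4, labels=False).astype(str) + "|" + df["gender"]
        worst = 1.0
        for seed in range(30):
            train, _ = stratified_split(clin, 0.75, seed=seed)
            in_train = df.index.isin(train)
            tab = pd.crosstab(bins, in_train)
            _, p, _, _ = stats.chi2_contingency(tab)
            worst = min(worst, p)
        assert worst > 0.01

    def test_singleton_stratum_goes_to_training(self):
        clin = clinical_from(
            age=[30.0] * 10 + [90.0],
            gender=["female"] * 10 + ["male"],
        )
        with pytest.warns(UserWarning, match="singleton"):
            train, valid = stratified_split(clin, 0.5, seed=0)
        assert "s10" in train

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2])
    def test_fraction_domain(self, bad):
        with pytest.raises(ValueError):
            stratified_split(self.make_cohort(10), bad)


class TestQpcr:
    def test_constant_delta_ct_flagged(self):
        ct = pd.DataFrame(
            {"GAPDH": [20.0, 21.0, 22.0], "A": [20.0, 21.0, 22.0], "B": [18.0, 19.0, 21.0]},
            index=pd.Index(["p1", "p2", "p3"], name="sample_id"),
        )
        with pytest.warns(UserWarning, match="constant"):
            z = qpcr_to_expression(QpcrPanel(ct=ct))
        assert (z.values.loc["A"] == 0).all()
        assert "A" in z.constant_genes

    def test_missing_reference_sample_dropped(self):
        ct = pd.DataFrame(
            {"GAPDH": [20.0, np.nan, 22.0], "A": [15.0, 16.0, 18.0]},
            index=pd.Index(["p1", "p2", "p3"], name="sample_id"),
        )
        with pytest.warns(UserWarning, match="reference"):
            z = qpcr_to_expression(QpcrPanel(ct=ct))
        assert z.sample_ids == ["p1", "p3"]

    def test_reference_gene_required(self):
        ct = pd.DataFrame({"A": [1.0, 2.0]}, index=["p1", "p2"])
        with pytest.raises(ValueError):
            QpcrPanel(ct=ct, reference_gene="GAPDH")

    def test_qpcr_path_consistent_with_expression_path(self, strong_cohort, strong_pipeline):
        """Ct built as c - log2(expression) must score like the expression
        path: delta-Ct is affine in log2 expression and z-scoring removes the
        affine terms (Spearman rho >= 0.9 over 20 samples)."""
        model = strong_pipeline.model
        genes = model.signature.genes
        expr = strong_cohort.expression.values
        samples = expr.columns[:20]
        sub = expr.loc[genes, samples]
        ct = (30.0 - np.log2(sub)).T  # samples x genes
        ct["GAPDH"] = 18.0
        z = qpcr_to_expression(QpcrPanel(ct=ct))
        qpcr_scores = score_samples(model, z, normalization="cohort")
        from pgskit import ExpressionMatrix

        expr_scores = score_samples(
            model,
            ExpressionMatrix(expr[samples], scale="raw"),
            normalization="cohort",
        )
        rho = stats.spearmanr(qpcr_scores["score"], expr_scores["score"]).statistic
        assert rho >= 0.9

    def test_small_panel_stratification_counts(self, strong_cohort, strong_pipeline):
        """A 6-sample panel built from the most extreme latent risks splits
        5 high / 1 low when constructed that way."""
        model = strong_pipeline.model
        genes = model.signature.genes
        z = strong_cohort.latent_risk.sort_values()
        chosen = list(z.index[:1]) + list(z.index[-5:])  # 1 low, 5 high
        sub = strong_cohort.expression.values.loc[genes, chosen]
        ct = (30.0 - np.log2(sub)).T
        ct["GAPDH"] = 18.0
        panel_z = qpcr_to_expression(QpcrPanel(ct=ct))
        scores = score_samples(model, panel_z, normalization="cohort")
        assert (scores["group"] == "high").sum() >= 4
        assert (scores["group"] == "low").sum() >= 1


class TestPipelineOrchestration:
    def test_strong_signal_discovery(self, strong_cohort, strong_pipeline):
        sig = set(strong_pipeline.signature.genes)
        planted = strong_cohort.planted_genes
        assert sig <= planted  # boosted ubiquity keeps the pool inside the planted set
        assert len(sig) >= 5
        assert strong_pipeline.report["auc_oof"] >= 0.70

    def test_null_cohort_auc_within_null_band(self, null_pipeline):
        assert 0.40 <= null_pipeline.report["auc_oof"] <= 0.60

    def test_manifest_records_stages(self, strong_pipeline):
        names = [s["name"] for s in strong_pipeline.manifest["stages"]]
        assert names == [
            "candidate_selection",
            "essentiality_screen",
            "signature_assembly",
            "risk_model",
            "scoring",
            "evaluation",
        ]
        assert strong_pipeline.manifest["seed"] == 1

    def test_rerun_is_bit_identical(self, small_cohort, tmp_path):
        from pgskit import run_pipeline

        c = small_cohort
        out_a = tmp_path / "a"
        out_b = tmp_path / "b"
        run_pipeline(c.expression, c.clinical, c.screen, seed=3, out_dir=out_a)
        run_pipeline(c.expression, c.clinical, c.screen, seed=3, out_dir=out_b)
        for name in ("pool.json", "essentiality.tsv", "signature.json",
                     "model.json", "scores.tsv", "report.json"):
            assert (out_a / name).read_text() == (out_b / name).read_text()

    def test_stage_failure_names_stage(self, small_cohort):
        from pgskit import run_pipeline
        from pgskit.cohort import ShrnaScreen

        c = small_cohort
        # positive-only screen -> no survival genes -> essentiality stage fails
        pos = c.screen.data.copy()
        pos["log2_fc"] = np.abs(pos["log2_fc"]) + 0.1
        with pytest.raises(RuntimeError, match="essentiality_screen"):
            run_pipeline(c.expression, c.clinical, ShrnaScreen(pos), seed=0)
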