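"""Per-ASV diet-association screen.

For every retained ASV (mean relative abundance strictly above a threshold,
0.01% by default) and every candidate model, a quasibinomial GLM of the
ASV's relative abundance on diet covariates is fitted.  Per model, the
count of nominally significant fits is tested against the 5% null with the
exceedance χ² test, and Benjamini–Hochberg q-values are computed across
ASVs.  Per-coefficient signs of significant ASVs populate a sign matrix,
optionally grouped by bacterial class.

Design matrices z-standardize each diet metric across the fitted samples;
quadratic terms are squares of the standardized values.  This keeps
coefficients comparable across metrics and keeps a quadratic term from
being collinear with its linear part when the metric is far from zero
(δ34S ≈ 18 permil), without changing any model-level test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import (
    ExceedanceResult,
    QuasibinomialLogit,
    bh_fdr,
    exceedance_test,
    permutation_f_pvalue,
)
from .io import DEFAULT_SEED
from .io import FeatureTable, logger

METRIC_COLUMNS = ("alpha", "trophic_position", "d34s")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: a name and an ordered tuple of terms.

    A term is a diet-metric column name, optionally suffixed ``^2`` for the
    quadratic of the standardized metric, e.g. ``("alpha", "d34s^2")``.
    """

    name: str
    terms: tuple[str, ...]

    def __post_init__(self):
        if not self.terms:
            raise ValueError("a model needs at least one non-intercept term")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError(f"duplicate terms in model {self.name!r}")
        for t in self.terms:
            if self._base(t) not in METRIC_COLUMNS:
                raise ValueError(
                    f"unknown term {t!r}; bases must be one of {METRIC_COLUMNS}"
                )

    @staticmethod
    def _base(term: str) -> str:
        return term[:-2] if term.endswith("^2") else term

    def design_matrix(self, metrics: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        """Intercept + standardized-term columns for the given samples."""
        cols = [np.ones(len(metrics))]
        names = ["intercept"]
        for t in self.terms:
            base = self._base(t)
            x = metrics[base].to_numpy(dtype=float)
            sd = x.std(ddof=1)
            if sd == 0:
                raise ValueError(f"metric {base!r} is constant; cannot standardize")
            z = (x - x.mean()) / sd
            cols.append(z**2 if t.endswith("^2") else z)
            names.append(t)
        return np.column_stack(cols), names


#: The four candidate models of the screen: each single metric linearly,
#: plus littoral carbon combined with the quadratic of δ34S.
DEFAULT_MODELS = (
    ModelSpec("alpha", ("alpha",)),
    ModelSpec("trophic_position", ("trophic_position",)),
    ModelSpec("d34s", ("d34s",)),
    ModelSpec("alpha+d34s^2", ("alpha", "d34s^2")),
)


class DietMicrobiomeScreen:
    """Quasibinomial GLM screen of ASV relative abundances on diet metrics.

    Parameters
    ----------
    table : FeatureTable
        QC'd counts.  Samples must map 1:1 onto birds in ``metrics``; by
        default sample ids are bird ids, or pass ``metadata`` to map via its
        ``bird_id`` column (restricting to first-sampling-point, sexed,
        non-control samples — one sample per bird).
    metrics : DataFrame indexed by bird_id with alpha/trophic_position/d34s.
    models : iterable of ModelSpec, default the four-candidate set.
    min_mean_rel_abund : strict lower bound on mean relative abundance.
    weights : "unit" (default; abundances were normalized first) or "depth"
        (per-sample read totals as binomial weights).
    """

    def __init__(
        self,
        table: FeatureTable,
        metrics: pd.DataFrame,
        models=None,
        metadata: pd.DataFrame | None = None,
        min_mean_rel_abund: float = 1e-4,
        weights: str = "unit",
    ):
        if weights not in ("unit", "depth"):
            raise ValueError("weights must be 'unit' or 'depth'")
        self.models = tuple(models) if models is not None else DEFAULT_MODELS
        self.min_mean_rel_abund = float(min_mean_rel_abund)
        self.weights = weights

        if metadata is not None:
            keep = []
            for s in table.sample_ids:
                if s not in metadata.index:
                    continue
                row = metadata.loc[s]
                if (
                    not bool(row["is_negative_control"])
                    and int(row["sampling_point"]) == 1
                    and row["sex"] in ("female", "male")
                    and str(row["bird_id"]) in metrics.index
                ):
                    keep.append(s)
            bird_of = {s: str(metadata.at[s, "bird_id"]) for s in keep}
        else:
            keep = [s for s in table.sample_ids if s in metrics.index]
            bird_of = {s: s for s in keep}
        unmatched = [s for s in table.sample_ids if s not in bird_of]
        if metadata is None and unmatched:
            raise ValueError(
                f"samples without diet metrics (and no metadata to map them): {unmatched}"
            )
        if len(keep) < 5:
            raise ValueError(f"only {len(keep)} usable samples; need at least 5")
        birds = [bird_of[s] for s in keep]
        if len(set(birds)) != len(birds):
            raise ValueError("multiple samples map to the same bird; one sample per bird required")

        self.table = FeatureTable(table.counts.loc[keep])
        self.metrics = metrics.loc[birds].set_axis(keep, axis=0)
        if self.metrics[list(METRIC_COLUMNS)].isna().any().any():
            bad = self.metrics.index[self.metrics[list(METRIC_COLUMNS)].isna().any(axis=1)]
            raise ValueError(f"incomplete diet metrics for samples: {list(bad)}")

    def fit(
        self,
        alpha_level: float = 0.05,
        max_iter: int = 100,
        tol: float = 1e-8,
        p_mode: str = "permutation",
        n_perm: int = 999,
        seed: int | None = DEFAULT_SEED,
    ) -> "ScreenResults":
        """Fit every model to every retained feature.

        ``p_mode`` selects the model-level p-value: ``"permutation"``
        (default) calibrates the quasi-F statistic by shuffling the
        covariate labels (``n_perm`` permutations, seeded), which keeps the
        screen's false-positive rate at its nominal level even for sparse,
        heavily overdispersed features where the analytic F reference is
        anti-conservative; ``"analytic"`` uses the parametric quasi-F p.
        The analytic p is always recorded as ``p_model_analytic``.
        """
        if p_mode not in ("permutation", "analytic"):
            raise ValueError("p_mode must be 'permutation' or 'analytic'")
        if p_mode == "permutation" and self.weights == "depth":
            raise ValueError("permutation p-values require unit weights")
        rel = self.table.relative_abundance()
        mean_rel = rel.mean(axis=0)
        kept = mean_rel.index[mean_rel > self.min_mean_rel_abund].tolist()
        if not kept:
            raise ValueError(
                f"no features exceed mean relative abundance {self.min_mean_rel_abund}"
            )
        logger.info(
            "screening %d of %d features (mean relative abundance > %g) "
            "across %d samples and %d models",
            len(kept), rel.shape[1], self.min_mean_rel_abund,
            rel.shape[0], len(self.models),
        )
        w = (
            self.table.sample_depths().to_numpy(dtype=float)
            if self.weights == "depth"
            else None
        )
        rng = np.random.default_rng(seed)
        n_samples = self.table.shape[0]
        rows = []
        for spec in self.models:
            X, names = spec.design_matrix(self.metrics)
            if p_mode == "permutation":
                perms = np.vstack(
                    [rng.permutation(n_samples) for _ in range(n_perm)]
                )
            for fid in kept:
                y = rel[fid].to_numpy(dtype=float)
                res = QuasibinomialLogit(y, X, var_weights=w, exog_names=names).fit(
                    max_iter=max_iter, tol=tol
                )
                if p_mode == "permutation":
                    p_model = permutation_f_pvalue(y, X, perms)
                else:
                    p_model = res.f_pvalue
                rec = {
                    "model": spec.name,
                    "feature_id": fid,
                    "p_model": p_model,
                    "p_model_analytic": res.f_pvalue,
                    "phi": res.scale,
                    "converged": res.converged,
                }
                for j, term in enumerate(names[1:], start=1):
                    rec[f"coef[{term}]"] = res.params[j]
                    rec[f"p[{term}]"] = res.pvalues[j]
                rows.append(rec)
        per_feature = pd.DataFrame(rows)

        exceedance: dict[str, ExceedanceResult] = {}
        qcols = []
        for spec in self.models:
            sub = per_feature[per_feature["model"] == spec.name]
            conv = sub[sub["converged"]]
            n_dropped = len(sub) - len(conv)
            if n_dropped:
                logger.warning(
                    "model %r: %d non-converged fits excluded from the exceedance test",
                    spec.name, n_dropped,
                )
            if p_mode == "permutation":
                # a level-alpha permutation test rejects when p <= alpha
                # (discrete p; this is what gives the test exact size)
                n_sig = int((conv["p_model"] <= alpha_level).sum())
            else:
                n_sig = int((conv["p_model"] < alpha_level).sum())
            ex = exceedance_test(n_sig, len(conv))
            ex.model = spec.name
            ex.alpha_level = alpha_level
            exceedance[spec.name] = ex
            q = pd.Series(np.nan, index=sub.index)
            q.loc[conv.index] = bh_fdr(conv["p_model"].to_numpy())
            qcols.append(q)
        per_feature["q"] = pd.concat(qcols).sort_index()
        return ScreenResults(
            screen=self,
            per_feature=per_feature,
            exceedance=exceedance,
            alpha_level=alpha_level,
            n_features_tested=len(kept),
            p_mode=p_mode,
        )


@dataclass
class ScreenResults:
    """Fitted screen: per-feature fits, exceedance tests, and q-values."""

    screen: DietMicrobiomeScreen
    per_feature: pd.DataFrame
    exceedance: dict[str, ExceedanceResult]
    alpha_level: float
    n_features_tested: int
    p_mode: str = "permutation"

    def _is_sig(self, p):
        return p <= self.alpha_level if self.p_mode == "permutation" else p < self.alpha_level

    def summary(self) -> pd.DataFrame:
        """One row per model: the machine twin of a per-model results table.

        Percentages are of converged fits; ``pct_significant`` uses the
        model-level quasi-F p, ``pct_fdr_significant`` the BH q.
        """
        rows = []
        for name, ex in self.exceedance.items():
            sub = self.per_feature[self.per_feature["model"] == name]
            n_q = int((sub["q"] < self.alpha_level).sum())
            rows.append(
                {
                    "model": name,
                    "n_models": ex.n_models,
                    "n_significant": ex.n_significant,
                    "pct_significant": 100.0 * ex.proportion,
                    "chi2": ex.chi2,
                    "p_chi2": ex.p_value,
                    "n_fdr_significant": n_q,
                    "pct_fdr_significant": 100.0 * n_q / ex.n_models,
                }
            )
        return pd.DataFrame(rows).set_index("model")

    def significant_features(self, model: str, fdr: bool = False) -> list[str]:
        sub = self.per_feature[self.per_feature["model"] == model]
        if fdr:
            return sub.loc[sub["q"] < self.alpha_level, "feature_id"].tolist()
        return sub.loc[self._is_sig(sub["p_model"]), "feature_id"].tolist()

    def sign_matrix(
        self, model: str, taxonomy: pd.DataFrame | None = None, fdr: bool = False
    ) -> pd.DataFrame:
        """Signs (+1/−1) of each term's coefficient for significant ASVs.

        Rows are significant features (model-level p, or q when ``fdr``);
        one column per term, plus a ``class`` column when taxonomy is given
        (the row grouping of the sign-matrix figure).
        """
        spec = next(m for m in self.screen.models if m.name == model)
        sub = self.per_feature[self.per_feature["model"] == model].set_index("feature_id")
        mask = sub["q"] < self.alpha_level if fdr else self._is_sig(sub["p_model"])
        sig = sub[mask]
        out = pd.DataFrame(
            {t: np.sign(sig[f"coef[{t}]"]).astype(int) for t in spec.terms},
            index=sig.index,
        )
        if taxonomy is not None:
            out["class"] = [
                taxonomy.at[f, "class"] if f in taxonomy.index else ""
                for f in out.index
            ]
            out = out.sort_values("class")
        return out

    def plot_sign_matrix(self, model: str, taxonomy=None, ax=None):
        """Bar-matrix of positive (red) / negative (blue) associations."""
        import matplotlib.pyplot as plt

        sm = self.sign_matrix(model, taxonomy=taxonomy)
        terms = [c for c in sm.columns if c != "class"]
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 2 + 0.2 * len(terms)))
        for i, term in enumerate(terms):
            for j, (fid, row) in enumerate(sm.iterrows()):
                color = "firebrick" if row[term] > 0 else "steelblue"
                ax.bar(j, 0.8, bottom=i, width=0.9, color=color)
        ax.set_yticks([i + 0.4 for i in range(len(terms))])
        ax.set_yticklabels(terms)
        ax.set_xlabel("significant ASVs")
        ax.set_title(f"coefficient signs, model {model!r}")
        return ax
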