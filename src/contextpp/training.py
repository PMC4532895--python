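"""Model training and evaluation: bootstrap stepwise-AIC feature selection,
per-site-type OLS fits, scaling-percentile estimation, and prediction
evaluation (r-squared, sliding top-N response).

Training rows are (mRNA, experiment) pairs in which the mRNA carries a
single canonical 3'-UTR site to the perturbed sRNA and has one dominant
tandem isoform (>= 90% of 3P-seq tags), so each normalized fold change can
be attributed to one site in a well-defined 3'-UTR context.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .features import ScalingTable
from .profiles import IsoformProfile
from .scoring import DEFAULT_CAPS, SiteTypeModel
from .sites import find_sites
from .types import CANONICAL_SITE_TYPES, SITE_OFF6, MirnaFamily, TranscriptModel

__all__ = [
    "aic",
    "gaussian_loglik",
    "StepwiseAICRegressor",
    "stepwise_select",
    "TrainingSet",
    "SelectionReport",
    "bootstrap_selection",
    "fit_site_model",
    "fit_scaling",
    "partial_correlation",
    "evaluate_r2",
    "top_n_response",
    "select_training_mrnas",
    "seed_match_information_bits",
    "information_capture_fraction",
    "false_positive_bound",
    "top_prediction_count",
]


# ---------------------------------------------------------------------------
# AIC and stepwise search


def gaussian_loglik(rss: float, n: int) -> float:
    """Maximized Gaussian log-likelihood of an OLS fit with residual sum of
    squares ``rss`` on ``n`` observations."""
    rss = max(rss, 1e-300)
    return -0.5 * n * (np.log(2 * np.pi) + np.log(rss / n) + 1.0)


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, -2 ln L + 2k (smaller is better).

    Selection *minimizes* this quantity: the likelihood term rewards fit,
    the 2k term charges for model complexity.
    """
    return -2.0 * loglik + 2.0 * k


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


class StepwiseAICRegressor(RegressorMixin, BaseEstimator):
    """Linear regression with bidirectional stepwise feature selection by AIC.

    Starting from an intercept-only model (or the full model), the search
    repeatedly applies the single feature addition or removal that most
    decreases the AIC of the Gaussian OLS fit, stopping when no move
    improves it.  The search is deterministic given the column order.

    Attributes set by :meth:`fit` — ``selected_features_`` (column names in
    selection order), ``coef_`` / ``intercept_``, ``aic_``.
    """

    def __init__(self, start: str = "intercept", max_steps: int = 200):
        self.start = start
        self.max_steps = max_steps

    def fit(self, X, y):
        X = pd.DataFrame(X).reset_index(drop=True)
        X.columns = [str(c) for c in X.columns]
        y = np.asarray(y, dtype=float)
        n = len(y)
        if n <= X.shape[1]:
            raise ValueError("need more rows than candidate features")
        cols = list(X.columns)
        Xa = X.to_numpy(dtype=float)
        ones = np.ones((n, 1))
        # floor the RSS at a perfect-fit tolerance: once a model explains the
        # response to numerical precision, further additions only pay the 2k
        # complexity charge instead of chasing rounding noise in log(RSS)
        tss = float(np.sum((y - y.mean()) ** 2))
        rss_floor = tss * 1e-12 + 1e-300

        def fit_aic(idx: tuple[int, ...]) -> float:
            M = np.hstack([ones, Xa[:, list(idx)]]) if idx else ones
            rss = max(_ols_rss(M, y), rss_floor)
            return aic(gaussian_loglik(rss, n), k=len(idx) + 1)

        current: tuple[int, ...] = tuple(range(len(cols))) if self.start == "full" else ()
        current_aic = fit_aic(current)
        cache: dict[tuple[int, ...], float] = {current: current_aic}
        for _ in range(self.max_steps):
            moves: list[tuple[float, tuple[int, ...]]] = []
            in_set = set(current)
            for j in range(len(cols)):  # additions
                if j not in in_set:
                    cand = tuple(list(current) + [j])
                    moves.append((cache.setdefault(cand, fit_aic(cand)), cand))
            for j in current:  # removals
                cand = tuple(i for i in current if i != j)
                moves.append((cache.setdefault(cand, fit_aic(cand)), cand))
            if not moves:
                break
            best_aic, best_set = min(moves, key=lambda m: (m[0], m[1]))
            if best_aic < current_aic - 1e-9:
                current, current_aic = best_set, best_aic
            else:
                break

        self.selected_features_ = [cols[j] for j in current]
        M = np.hstack([ones, Xa[:, list(current)]]) if current else ones
        beta, _, rank, _ = np.linalg.lstsq(M, y, rcond=None)
        if rank < M.shape[1]:
            warnings.warn("rank-deficient design after selection; aliased columns dropped")
        self.intercept_ = float(beta[0])
        self.coef_ = pd.Series(beta[1:], index=self.selected_features_)
        self.aic_ = current_aic
        self._columns = cols
        return self

    def predict(self, X):
        X = pd.DataFrame(X)
        X.columns = [str(c) for c in X.columns]
        pred = np.full(len(X), self.intercept_)
        for name, b in self.coef_.items():
            pred += b * X[name].to_numpy(dtype=float)
        return pred


def stepwise_select(design: pd.DataFrame, response, candidates: Sequence[str] | None = None) -> list[str]:
    """Bidirectional stepwise-AIC selection from an intercept-only start;
    returns the selected feature names."""
    design = pd.DataFrame(design)
    if candidates is not None:
        design = design[list(candidates)]
    reg = StepwiseAICRegressor().fit(design, response)
    return reg.selected_features_


# ---------------------------------------------------------------------------
# bootstrap selection


@dataclass
class TrainingSet:
    """Per site type: design matrix of candidate features, response vector
    of normalized log2 fold changes, and per-row experiment labels."""

    per_type: dict[str, tuple[pd.DataFrame, pd.Series, pd.Series]]

    def site_types(self) -> list[str]:
        return list(self.per_type)


@dataclass
class SelectionReport:
    frequencies: pd.DataFrame  # features x site types, fraction of bootstraps selected
    robust_set: list[str]
    heldout_r2: pd.DataFrame  # bootstraps x site types

    def frequency(self, feature: str, site_type: str) -> float:
        return float(self.frequencies.loc[feature, site_type])


def bootstrap_selection(
    training_set: TrainingSet,
    B: int = 1000,
    train_frac: float = 0.70,
    seed: int | None = None,
    *,
    robust_threshold: float = 0.99,
    robust_min_types: int = 2,
) -> SelectionReport:
    """Stepwise selection over ``B`` bootstrap samples per site type.

    Each sample draws ``train_frac`` of the rows of every experiment
    (stratified, without replacement); the remaining rows form the held-out
    set on which the selected model's r-squared is recorded.  The robust set
    contains features selected in at least ``robust_threshold`` of samples
    for at least ``robust_min_types`` site types.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap samples")
    rng = np.random.default_rng(seed)
    site_types = training_set.site_types()
    all_features = sorted(
        {c for X, _, _ in training_set.per_type.values() for c in X.columns}
    )
    freq = pd.DataFrame(0.0, index=all_features, columns=site_types)
    r2 = pd.DataFrame(np.nan, index=range(B), columns=site_types)

    for st in site_types:
        X, y, exps = training_set.per_type[st]
        X = X.reset_index(drop=True)
        y = pd.Series(np.asarray(y, dtype=float))
        exps = pd.Series(np.asarray(exps)).reset_index(drop=True)
        counts = pd.Series(0.0, index=X.columns)
        by_exp = {e: np.flatnonzero(exps.to_numpy() == e) for e in exps.unique()}
        for b in range(B):
            train_idx: list[int] = []
            for e, idx in by_exp.items():
                n_train = int(round(train_frac * len(idx)))
                take = rng.choice(idx, size=n_train, replace=False)
                train_idx.extend(take.tolist())
            train_idx = np.array(sorted(train_idx))
            test_mask = np.ones(len(X), dtype=bool)
            test_mask[train_idx] = False
            reg = StepwiseAICRegressor().fit(X.iloc[train_idx], y.iloc[train_idx])
            for f in reg.selected_features_:
                counts[f] += 1
            if test_mask.sum() >= 3:
                pred = reg.predict(X.loc[test_mask])
                obs = y[test_mask].to_numpy()
                if np.std(pred) > 0 and np.std(obs) > 0:
                    r2.loc[b, st] = evaluate_r2(pred, obs)
        freq.loc[counts.index, st] = counts / B

    robust = [
        f
        for f in all_features
        if (freq.loc[f] >= robust_threshold).sum() >= robust_min_types
    ]
    return SelectionReport(frequencies=freq, robust_set=robust, heldout_r2=r2)


# ---------------------------------------------------------------------------
# final fits


def drop_aliased_columns(X: pd.DataFrame) -> list[str]:
    """Columns to keep for a full-rank design (with intercept): greedily
    retains, in order, every column that raises the rank of the design.
    Constant columns and exact linear combinations of earlier columns are
    dropped — e.g. the target position-8 identity of 7-8mer-m8 sites, which
    is the Watson-Crick complement of sRNA position 8 and therefore aliased
    with it."""
    n = len(X)
    basis = np.ones((n, 1))
    kept: list[str] = []
    for c in X.columns:
        cand = np.column_stack([basis, X[c].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand) > basis.shape[1]:
            basis = cand
            kept.append(c)
    return kept


def fit_site_model(
    design: pd.DataFrame,
    response,
    site_type: str,
    *,
    cap: float | None = None,
) -> tuple[SiteTypeModel, pd.DataFrame]:
    """OLS fit of one site type on the full training data (no held-out
    split).  Returns the model (with its score cap attached) and the 95%
    confidence intervals of the coefficients (rows: intercept + features)."""
    X = pd.DataFrame(design)
    Xc = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("singular design matrix")
    res = sm.OLS(np.asarray(response, dtype=float), Xc).fit()
    names = ["intercept"] + list(X.columns)
    ci = pd.DataFrame(res.conf_int(alpha=0.05), index=names, columns=["low", "high"])
    ci["estimate"] = res.params
    model = SiteTypeModel(
        site_type=site_type,
        intercept=float(res.params[0]),
        coefficients=dict(zip(X.columns, map(float, res.params[1:]))),
        cap=DEFAULT_CAPS[site_type] if cap is None else cap,
    )
    return model, ci


def fit_scaling(raw_table: pd.DataFrame, *, min_values: int = 20) -> ScalingTable:
    """Scaling anchors from a long-form table with columns
    ``feature, site_type, value``: the 5th/95th percentiles (linear
    interpolation) per (feature, site type)."""
    required = {"feature", "site_type", "value"}
    if not required <= set(raw_table.columns):
        raise ValueError(f"raw table needs columns {sorted(required)}")
    table = {}
    for (f, st), grp in raw_table.groupby(["feature", "site_type"]):
        vals = grp["value"].dropna().to_numpy(dtype=float)
        if len(vals) < min_values:
            raise ValueError(f"({f}, {st}): only {len(vals)} values, need {min_values}")
        p5, p95 = np.percentile(vals, [5, 95], method="linear")
        if p95 <= p5:
            raise ValueError(f"({f}, {st}): degenerate percentiles (p5 == p95)")
        table[(f, st)] = (float(p5), float(p95))
    return ScalingTable(table)


# ---------------------------------------------------------------------------
# evaluation


def partial_correlation(x, y, controls=None) -> float:
    """Pearson correlation between the residuals of x and y after linear
    regression on the control covariates (plain Pearson r with no controls)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if controls is None or (hasattr(controls, "__len__") and len(controls) == 0):
        rx, ry = x - x.mean(), y - y.mean()
    else:
        C = np.column_stack([np.ones(len(x)), np.asarray(controls, dtype=float)])
        rx = x - C @ np.linalg.lstsq(C, x, rcond=None)[0]
        ry = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom < 1e-12:
        raise ValueError("degenerate residuals: partial correlation undefined")
    return float((rx @ ry) / denom)


def evaluate_r2(scores, observed) -> float:
    """Squared Pearson correlation between prediction scores and observed
    fold changes (mRNAs without a prediction should enter with the worst
    score in range before calling)."""
    scores = np.asarray(scores, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if np.std(scores) == 0 or np.std(observed) == 0:
        raise ValueError("zero variance input")
    r, _ = stats.pearsonr(scores, observed)
    return float(r * r)


def top_n_response(
    ranked: pd.DataFrame,
    fold_changes: Mapping | pd.Series,
    thresholds: Sequence[int],
    n_mirnas: int,
    resamples: int = 1000,
    seed: int | None = None,
    score_column: str = "cwcs",
    key_columns: tuple[str, str] = ("transcript_id", "family_id"),
) -> pd.DataFrame:
    """Median (and mean) cognate fold change of the top predictions at each
    sliding threshold, with a resampled 95% null band.

    A threshold t selects the t * n_mirnas best-scored predictions pooled
    across miRNAs.  Thresholds exceeding the number of predictions emit no
    row.  The null band is the 2.5/97.5 percentile of the median fold change
    of equally many randomly drawn mRNAs over ``resamples`` draws.
    """
    rng = np.random.default_rng(seed)
    ranked = ranked.sort_values(score_column, kind="mergesort")
    fc = np.array(
        [
            fold_changes[(row[key_columns[0]], row[key_columns[1]])]
            if not isinstance(fold_changes, pd.Series)
            else fold_changes.loc[(row[key_columns[0]], row[key_columns[1]])]
            for _, row in ranked.iterrows()
        ],
        dtype=float,
    )
    pool = np.asarray(list(fold_changes.values()) if isinstance(fold_changes, Mapping) else fold_changes.to_numpy(), dtype=float)
    rows = []
    for t in thresholds:
        k = int(t * n_mirnas)
        if k > len(ranked) or k < 1:
            continue
        top = fc[:k]
        null_medians = np.array(
            [np.median(rng.choice(pool, size=k, replace=False)) for _ in range(resamples)]
        )
        lo, hi = np.percentile(null_medians, [2.5, 97.5])
        rows.append(
            {
                "threshold": t,
                "n_predictions": k,
                "median_fc": float(np.median(top)),
                "mean_fc": float(np.mean(top)),
                "null_low": float(lo),
                "null_high": float(hi),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# training-set assembly


def select_training_mrnas(
    transcripts: Mapping[str, TranscriptModel],
    profiles: Mapping[str, IsoformProfile],
    family: MirnaFamily,
    *,
    dominant_fraction: float = 0.90,
) -> list[str]:
    """Transcripts eligible for single-site regression modeling: one
    dominant tandem isoform (>= 90% of tags) and exactly one canonical
    (non-offset) 3'-UTR site to the perturbed sRNA."""
    out = []
    for tid, t in transcripts.items():
        prof = profiles.get(tid)
        if prof is None or prof.dominant_fraction < dominant_fraction:
            continue
        canonical = [
            s
            for s in find_sites(t.utr3, family, transcript_id=tid)
            if s.site_type != SITE_OFF6
        ]
        if len(canonical) == 1:
            out.append(tid)
    return out


def training_set_from_simulation(
    sim,
    responses: pd.DataFrame | None = None,
    features: Sequence[str] | None = None,
) -> TrainingSet:
    """Assemble the per-site-type single-site training set from a simulated
    compendium: rows are (gene, experiment) pairs whose gene carries exactly
    one canonical site to the perturbed family; the response is the gene's
    (normalized) log2 fold change in that experiment."""
    from .features import design_columns

    rows = sim.site_rows
    if responses is None:
        responses = sim.compendium.Z
    if features is None:
        features = design_columns()
    counts = rows.groupby(["gene_id", "experiment_id"]).size()
    single = counts[counts == 1].index
    sel = rows.set_index(["gene_id", "experiment_id"]).loc[single].reset_index()
    per_type: dict[str, tuple[pd.DataFrame, pd.Series, pd.Series]] = {}
    for st, grp in sel.groupby("site_type"):
        y = pd.Series(
            [responses.loc[g, e] for g, e in zip(grp["gene_id"], grp["experiment_id"])],
            index=grp.index,
            dtype=float,
        )
        keep = y.notna()
        per_type[st] = (
            grp.loc[keep, list(features)].reset_index(drop=True),
            y[keep].reset_index(drop=True),
            grp.loc[keep, "experiment_id"].reset_index(drop=True),
        )
    return TrainingSet(per_type=per_type)


# ---------------------------------------------------------------------------
# worked-example arithmetic


def seed_match_information_bits(site_length_nt: int) -> float:
    """Information content of an exact site match: 2 bits per specified
    nucleotide (a canonical 6mer carries 12 bits, a 7mer 14 bits)."""
    if site_length_nt < 1:
        raise ValueError("site length must be positive")
    return 2.0 * site_length_nt


def information_capture_fraction(standalone_r2: float, delta_r2: float) -> float:
    """Fraction of the information potentially carried by molecular features
    that a model already captures, inferred from how little r-squared is
    lost when the conservation feature is removed: (standalone - delta) /
    standalone, where ``standalone_r2`` is the r-squared of conservation
    alone and ``delta_r2`` the drop from removing it from the full model."""
    if standalone_r2 <= 0:
        raise ValueError("standalone r2 must be positive")
    return (standalone_r2 - delta_r2) / standalone_r2


def false_positive_bound(positive_fold_change_fraction: float) -> float:
    """Upper bound on the false-positive fraction among top predictions:
    twice the fraction with positive fold change (false positives are
    equally likely to move either way)."""
    if not 0 <= positive_fold_change_fraction <= 0.5:
        raise ValueError("fraction must be in [0, 0.5]")
    return 2.0 * positive_fold_change_fraction


def top_prediction_count(threshold_per_mirna: int, n_mirnas: int) -> int:
    """Number of pooled predictions at a sliding threshold: the average
    per-miRNA threshold times the number of miRNAs."""
    return int(threshold_per_mirna * n_mirnas)
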