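"""Species-discrimination statistics for hook measurement tables.

Given a specimens x variables table with species labels (a "morpho
dataset"), this module reproduces the full statistical surface used to
separate diplozoid species on hook morphometry:

* per-species summaries (mean, SD, range) — :func:`summarize`;
* Kruskal-Wallis tests with pairwise post hoc comparisons per variable —
  :func:`kw_posthoc` (Dunn's z tests on the joint ranking, Bonferroni
  adjusted; pairwise Mann-Whitney available as an alternative);
* univariate tests of equality of group means (Wilks' Λ = SSW/SST and the
  equivalent one-way F) — :func:`equality_of_group_means`;
* forward stepwise linear discriminant analysis driven by the overall
  Wilks' Λ with F-to-enter / F-to-remove thresholds —
  :func:`stepwise_select`;
* canonical discriminant functions, group centroids and the pooled
  within-group structure matrix — :func:`fit_canonical`;
* Mahalanobis-rule classification with leave-one-out cross-validation —
  :func:`classify_loo`.

Conventions follow the common stepwise-LDA implementation in commercial
statistics packages: F-to-enter 3.84, F-to-remove 2.71, equal priors, and
cross-validation that refits coefficients per fold while keeping the
selected variable set fixed.  Multivariate analyses use listwise-complete
rows; summaries use available cases per variable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError
from .variables import VARIABLE_NAMES

__all__ = [
    "format_summary",
    "summarize",
    "kw_posthoc",
    "KWResult",
    "equality_of_group_means",
    "stepwise_select",
    "StepwiseResult",
    "fit_canonical",
    "DiscriminantModel",
    "classify_loo",
    "ClassificationTable",
]

DEFAULT_F_ENTER = 3.84
DEFAULT_F_REMOVE = 2.71
_TOLERANCE = 1e-3  # minimum within-group tolerance (1 - R^2) to enter


def _variable_columns(data: pd.DataFrame) -> list[str]:
    return [v for v in VARIABLE_NAMES if v in data.columns]


def _check_dataset(data: pd.DataFrame) -> None:
    if "species" not in data.columns:
        raise AnalysisError("dataset needs a 'species' column")
    if not _variable_columns(data):
        raise AnalysisError("dataset carries none of the known variables")


# ---------------------------------------------------------------------------
# summaries


def format_summary(mean: float, sd: float, low: float, high: float,
                   ndigits: int = 2) -> str:
    """Render the conventional "mean ± sd (low–high)" summary string."""
    return (f"{mean:.{ndigits}f} ± {sd:.{ndigits}f} "
            f"({low:.{ndigits}f}–{high:.{ndigits}f})")


def summarize(data: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    """Per-species, per-variable mean, SD (n−1), range and n.

    Returns a tidy frame with columns ``species, variable, mean, sd, low,
    high, n, formatted`` where ``formatted`` renders the conventional
    "mean ± sd (low–high)" string.  Uses available cases per variable.
    """
    _check_dataset(data)
    rows = []
    for species, grp in data.groupby("species", sort=False):
        for var in _variable_columns(data):
            vals = grp[var].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                continue
            if len(vals) == 1:
                warnings.warn(f"{species}/{var}: single observation, SD set to 0",
                              stacklevel=2)
                sd = 0.0
            else:
                sd = float(np.std(vals, ddof=1))
            mean, low, high = float(vals.mean()), float(vals.min()), float(vals.max())
            rows.append({
                "species": species, "variable": var,
                "mean": mean, "sd": sd, "low": low, "high": high, "n": len(vals),
                "formatted": format_summary(mean, sd, low, high, ndigits),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kruskal-Wallis with post hoc pairwise tests


@dataclass
class KWResult:
    """Kruskal-Wallis result for one variable with pairwise post hoc p's."""

    variable: str
    H: float
    p_global: float
    pairwise: dict[tuple[str, str], float]
    significant_pairs: set[tuple[str, str]] = field(default_factory=set)
    alpha: float = 0.05


def _exact_kw_p(groups: list[np.ndarray], h_obs: float) -> float:
    """Exact permutation p of the Kruskal-Wallis H by full enumeration.

    Feasible for small total N (the pooled observations are permuted over
    the group-size pattern)."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    n = len(pooled)
    idx = np.arange(n)
    count = 0
    total = 0
    for perm in itertools.permutations(idx):
        parts, start = [], 0
        for s in sizes:
            parts.append(pooled[list(perm[start:start + s])])
            start += s
        h = _kw_h(parts)
        total += 1
        if h >= h_obs - 1e-9:
            count += 1
    return count / total


def _kw_h(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H (0 when all observations are equal)."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    if tie == 0:
        return 0.0
    return float(h / tie)


def kw_posthoc(data: pd.DataFrame, variable: str, alpha: float = 0.05,
               method: str = "mannwhitney", p_method: str = "chi2") -> KWResult:
    """Kruskal-Wallis test plus pairwise post hoc species comparisons.

    ``method`` selects the pairwise follow-up: ``"mannwhitney"`` (pairwise
    exact rank-sum tests, the default) or ``"dunn"`` (z tests on the joint
    ranking with the tie-corrected variance); both are Bonferroni-adjusted
    over the k(k−1)/2 pairs.  Dunn's statistic compares mean joint ranks,
    so with a group ranked between the other two its z is bounded well
    below significance at group sizes this small (8/4/5) no matter how
    separated the samples are — hence the rank-sum default.
    ``p_method="exact"`` replaces the chi-square global p by full
    permutation enumeration (only sensible for N ≤ ~8).
    """
    _check_dataset(data)
    if variable not in data.columns:
        raise AnalysisError(f"unknown variable {variable!r}")
    sub = data[["species", variable]].dropna()
    species = list(dict.fromkeys(sub["species"]))
    groups = [sub.loc[sub["species"] == sp, variable].to_numpy(dtype=float)
              for sp in species]
    if len(groups) < 2:
        raise AnalysisError("kw_posthoc needs at least two species")
    if any(len(g) == 0 for g in groups):
        raise AnalysisError("every species needs at least one observation")

    h = _kw_h(groups)
    if p_method == "exact":
        p_global = _exact_kw_p(groups, h)
    else:
        p_global = float(sps.chi2.sf(h, df=len(groups) - 1))

    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term

    mean_ranks, start = {}, 0
    for sp, g in zip(species, groups):
        mean_ranks[sp] = ranks[start:start + len(g)].mean()
        start += len(g)

    pairs = list(itertools.combinations(species, 2))
    m = len(pairs)
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        na = len(sub.loc[sub["species"] == a])
        nb = len(sub.loc[sub["species"] == b])
        if method == "dunn":
            if base_var <= 0:
                p = 1.0
            else:
                se = np.sqrt(base_var * (1.0 / na + 1.0 / nb))
                z = (mean_ranks[a] - mean_ranks[b]) / se
                p = 2.0 * float(sps.norm.sf(abs(z)))
        elif method == "mannwhitney":
            ga = sub.loc[sub["species"] == a, variable].to_numpy(dtype=float)
            gb = sub.loc[sub["species"] == b, variable].to_numpy(dtype=float)
            if np.ptp(np.concatenate([ga, gb])) == 0:
                p = 1.0
            else:
                p = float(sps.mannwhitneyu(ga, gb, alternative="two-sided").pvalue)
        else:
            raise ValueError(f"unknown post hoc method {method!r}")
        pairwise[(a, b)] = min(1.0, p * m)

    significant = {pair for pair, p in pairwise.items() if p < alpha}
    return KWResult(variable=variable, H=h, p_global=p_global,
                    pairwise=pairwise, significant_pairs=significant, alpha=alpha)


# ---------------------------------------------------------------------------
# equality of group means (univariate Wilks' lambda / one-way F)


def equality_of_group_means(data: pd.DataFrame,
                            variables: list[str] | None = None) -> pd.DataFrame:
    """Univariate Wilks' Λ = SSW/SST and F per variable, listwise complete.

    Returns a frame with columns ``variable, wilks_lambda, F, df1, df2, p``
    sorted by ascending Λ.  ``df1 = k−1`` and ``df2 = N−k`` where N counts
    the listwise-complete rows.
    """
    _check_dataset(data)
    variables = variables or _variable_columns(data)
    sub = data[["species", *variables]].dropna()
    species = list(dict.fromkeys(sub["species"]))
    k = len(species)
    if k < 2:
        raise AnalysisError("need at least two species")
    n = len(sub)
    df1, df2 = k - 1, n - k
    rows = []
    grand = sub[variables].mean()
    for var in variables:
        x = sub[var].to_numpy(dtype=float)
        sst = float(((x - grand[var]) ** 2).sum())
        if sst <= 0:
            raise AnalysisError(f"{var}: zero total variance, Wilks' lambda undefined")
        ssw = 0.0
        for sp in species:
            g = sub.loc[sub["species"] == sp, var].to_numpy(dtype=float)
            ssw += float(((g - g.mean()) ** 2).sum())
        lam = ssw / sst
        f = (1 - lam) / lam * (df2 / df1) if lam > 0 else np.inf
        p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        rows.append({"variable": var, "wilks_lambda": lam, "F": f,
                     "df1": df1, "df2": df2, "p": p})
    return pd.DataFrame(rows).sort_values("wilks_lambda", ignore_index=True)


# ---------------------------------------------------------------------------
# stepwise selection on the overall Wilks' lambda


def _group_arrays(sub: pd.DataFrame, variables: list[str]):
    x = sub[variables].to_numpy(dtype=float)
    labels = sub["species"].to_numpy()
    species = list(dict.fromkeys(labels))
    return x, labels, species


def _w_t(x: np.ndarray, labels: np.ndarray, species: list[str]):
    """Within-group (W) and total (T) SSCP matrices."""
    grand = x.mean(axis=0)
    t = (x - grand).T @ (x - grand)
    w = np.zeros_like(t)
    for sp in species:
        g = x[labels == sp]
        c = g - g.mean(axis=0)
        w += c.T @ c
    return w, t


def _sscp(sub: pd.DataFrame, variables: list[str]) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Within-group (W) and total (T) SSCP matrices over listwise rows."""
    x, labels, species = _group_arrays(sub, variables)
    w, t = _w_t(x, labels, species)
    return w, t, len(x), len(species)


def _lam_sub(w: np.ndarray, t: np.ndarray, idx: list[int]) -> float:
    """Overall Wilks' Λ for a variable subset, from precomputed full SSCPs."""
    if not idx:
        return 1.0
    ix = np.ix_(idx, idx)
    det_t = np.linalg.det(t[ix])
    if det_t <= 0:
        return np.nan
    return float(np.linalg.det(w[ix]) / det_t)


def _tolerance_sub(rw: np.ndarray, entered: list[int], candidate: int) -> float:
    """1 − R² of the candidate on the entered set in the pooled within space."""
    if not entered:
        return 1.0
    full = [*entered, candidate]
    det_full = np.linalg.det(rw[np.ix_(full, full)])
    det_sub = np.linalg.det(rw[np.ix_(entered, entered)])
    if det_sub <= 0:
        return 0.0
    return float(det_full / det_sub)


@dataclass
class StepwiseResult:
    selected: list[str]
    steps: pd.DataFrame  # step, action, variable, wilks_lambda, F
    warnings: list[str] = field(default_factory=list)


def stepwise_select(data: pd.DataFrame, variables: list[str] | None = None,
                    f_enter: float = DEFAULT_F_ENTER,
                    f_remove: float = DEFAULT_F_REMOVE,
                    max_steps: int = 100) -> StepwiseResult:
    """Forward stepwise variable selection minimizing the overall Wilks' Λ.

    At each step the candidate giving the smallest overall Λ enters if its
    F-to-enter (from the partial-Λ ratio, df (k−1, N−k−p)) reaches
    ``f_enter``; after each entry, entered variables whose F-to-remove
    falls below ``f_remove`` leave.  Candidates whose within-group
    tolerance (1−R² on the entered set) is below 0.001 are skipped with a
    logged warning.
    """
    _check_dataset(data)
    variables = variables or _variable_columns(data)
    if len(variables) < 2:
        raise AnalysisError("stepwise selection needs at least two candidates")
    sub = data[["species", *variables]].dropna()
    x, labels, species = _group_arrays(sub, variables)
    k, n = len(species), len(x)
    if k < 2:
        raise AnalysisError("need at least two species")
    wf, tf = _w_t(x, labels, species)
    d = np.sqrt(np.diag(wf))
    with np.errstate(invalid="ignore", divide="ignore"):
        rw = np.where(np.outer(d, d) > 0, wf / np.outer(d, d), 0.0)

    entered: list[int] = []
    log_rows = []
    notes: list[str] = []
    step = 0
    while step < max_steps:
        step += 1
        lam_now = _lam_sub(wf, tf, entered)
        p = len(entered)
        best = None
        for ci, cand in enumerate(variables):
            if ci in entered:
                continue
            tol = _tolerance_sub(rw, entered, ci)
            if tol < _TOLERANCE:
                notes.append(f"step {step}: {cand} skipped (tolerance {tol:.2e})")
                continue
            lam_new = _lam_sub(wf, tf, [*entered, ci])
            if not np.isfinite(lam_new) or lam_new <= 0:
                notes.append(f"step {step}: {cand} skipped (singular SSCP)")
                continue
            ratio = lam_new / lam_now
            df2 = n - k - p
            if df2 <= 0:
                continue
            f_in = (1 - ratio) / ratio * df2 / (k - 1)
            if best is None or lam_new < best[1]:
                best = (ci, lam_new, f_in)
        changed = False
        if best is not None and best[2] >= f_enter:
            entered.append(best[0])
            log_rows.append({"step": step, "action": "enter",
                             "variable": variables[best[0]],
                             "wilks_lambda": best[1], "F": best[2]})
            changed = True
            # removal pass
            removed = True
            while removed and len(entered) > 1:
                removed = False
                lam_full = _lam_sub(wf, tf, entered)
                p = len(entered)
                worst = None
                for vi in entered:
                    rest = [j for j in entered if j != vi]
                    lam_rest = _lam_sub(wf, tf, rest)
                    ratio = lam_full / lam_rest
                    df2 = n - k - (p - 1)
                    f_out = (1 - ratio) / ratio * df2 / (k - 1)
                    if worst is None or f_out < worst[1]:
                        worst = (vi, f_out)
                if worst is not None and worst[1] < f_remove:
                    entered.remove(worst[0])
                    log_rows.append({"step": step, "action": "remove",
                                     "variable": variables[worst[0]],
                                     "wilks_lambda": _lam_sub(wf, tf, entered),
                                     "F": worst[1]})
                    removed = True
        if not changed:
            break

    steps = pd.DataFrame(log_rows,
                         columns=["step", "action", "variable", "wilks_lambda", "F"])
    return StepwiseResult(selected=[variables[i] for i in entered],
                          steps=steps, warnings=notes)


# ---------------------------------------------------------------------------
# canonical discriminant functions


@dataclass
class DiscriminantModel:
    """Fitted canonical discriminant functions over a selected variable set."""

    selected: list[str]
    species: list[str]
    coefficients: np.ndarray          # (p, m) raw canonical coefficients
    constants: np.ndarray             # (m,) so scores are centred on the grand mean
    eigenvalues: np.ndarray           # (m,)
    centroids: pd.DataFrame           # species x functions
    pooled_within_cov: np.ndarray     # (p, p), df = N - k
    group_means: pd.DataFrame         # species x selected variables
    priors: dict[str, float]
    structure_matrix: pd.DataFrame    # all candidate variables x functions

    @property
    def n_functions(self) -> int:
        return self.coefficients.shape[1]

    def scores(self, data: pd.DataFrame) -> np.ndarray:
        x = data[self.selected].to_numpy(dtype=float)
        return x @ self.coefficients + self.constants


def _pooled_stats(sub: pd.DataFrame, variables: list[str]):
    species = list(dict.fromkeys(sub["species"]))
    w, t, n, k = _sscp(sub, variables)
    b = t - w
    means = sub.groupby("species", sort=False)[variables].mean()
    return species, w, b, means, n, k


def fit_canonical(data: pd.DataFrame, selected: list[str],
                  priors: dict[str, float] | None = None,
                  structure_variables: list[str] | None = None) -> DiscriminantModel:
    """Canonical discriminant functions for the selected variables.

    Solves the generalized eigenproblem B·v = λ·W·v (between / within SSCP)
    and scales each function so canonical scores have pooled within-group
    variance 1.  The structure matrix holds pooled within-group correlations
    of every candidate variable (entered or not) with each function.
    """
    _check_dataset(data)
    if not selected:
        raise AnalysisError("no variables selected")
    structure_variables = structure_variables or _variable_columns(data)
    sub = data[["species", *set(structure_variables) | set(selected)]].dropna()
    species, w, b, means, n, k = _pooled_stats(sub, selected)
    if k < 2:
        raise AnalysisError("need at least two species")
    m = min(k - 1, len(selected))

    try:
        from scipy.linalg import eigh
        evals, evecs = eigh(b, w)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise AnalysisError(f"singular pooled covariance over {selected}") from exc
    if not np.all(np.isfinite(evals)):
        raise AnalysisError(f"singular pooled covariance over {selected}")
    order = np.argsort(evals)[::-1][:m]
    evals = evals[order]
    vecs = evecs[:, order]            # v' W v = 1
    vecs = vecs * np.sqrt(n - k)      # -> v' (W/(N-k)) v = 1
    # sign convention: largest-magnitude coefficient positive
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]

    grand = sub[selected].mean().to_numpy(dtype=float)
    constants = -grand @ vecs
    x = sub[selected].to_numpy(dtype=float)
    scores = x @ vecs + constants

    cent = pd.DataFrame(
        [scores[(sub["species"] == sp).to_numpy()].mean(axis=0) for sp in species],
        index=pd.Index(species, name="species"),
        columns=[f"function{j + 1}" for j in range(m)],
    )

    # structure matrix: pooled within-group correlation variable <-> score
    struct = {}
    labels = sub["species"].to_numpy()
    sc_centered = scores.copy()
    for sp in species:
        msk = labels == sp
        sc_centered[msk] -= scores[msk].mean(axis=0)
    for var in structure_variables:
        v = sub[var].to_numpy(dtype=float).copy()
        for sp in species:
            msk = labels == sp
            v[msk] -= v[msk].mean()
        denom = np.sqrt((v ** 2).sum() * (sc_centered ** 2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            struct[var] = np.where(denom > 0, (v @ sc_centered) / denom, 0.0)
    structure = pd.DataFrame(struct, index=cent.columns).T
    structure.index.name = "variable"

    if priors is None:
        priors = {sp: 1.0 / k for sp in species}
    return DiscriminantModel(
        selected=list(selected), species=species,
        coefficients=vecs, constants=constants, eigenvalues=evals,
        centroids=cent, pooled_within_cov=w / (n - k),
        group_means=means, priors=priors,
        structure_matrix=structure,
    )


# ---------------------------------------------------------------------------
# classification with leave-one-out cross-validation


@dataclass
class ClassificationTable:
    """Original and cross-validated classification counts and percentages."""

    species: list[str]
    counts_original: pd.DataFrame
    counts_cv: pd.DataFrame
    percent_original: pd.DataFrame
    percent_cv: pd.DataFrame
    overall_original: float
    overall_cv: float
    skipped_folds: list[str] = field(default_factory=list)


def _mahalanobis_assign(x: np.ndarray, means: np.ndarray, cov: np.ndarray,
                        priors: np.ndarray, species: list[str]) -> str:
    inv = np.linalg.pinv(cov)
    d2 = np.array([
        float((x - mu) @ inv @ (x - mu)) - 2.0 * np.log(pr)
        for mu, pr in zip(means, priors)
    ])
    return species[int(np.argmin(d2))]


def _fit_rule_arrays(x: np.ndarray, labels: np.ndarray):
    species = list(dict.fromkeys(labels))
    means = np.vstack([x[labels == sp].mean(axis=0) for sp in species])
    w, _ = _w_t(x, labels, species)
    n, k = len(x), len(species)
    return species, means, w / (n - k)


def classify_loo(data: pd.DataFrame, selected: list[str],
                 priors: dict[str, float] | None = None) -> tuple[ClassificationTable, pd.DataFrame]:
    """Classify specimens by smallest Mahalanobis distance, plus LOO validation.

    Original classification uses the full-data pooled within-group
    covariance and group means; cross-validation refits both on each
    leave-one-out subset while keeping the selected variable set fixed.
    Returns the classification table and a per-specimen frame with
    assignments and canonical scores.
    """
    _check_dataset(data)
    sub = data[["specimen_id", "species", *selected]].dropna() \
        if "specimen_id" in data.columns else data[["species", *selected]].dropna()
    x = sub[selected].to_numpy(dtype=float)
    labels = sub["species"].to_numpy()
    species, means, cov = _fit_rule_arrays(x, labels)
    k = len(species)
    if priors is None:
        pri = np.full(k, 1.0 / k)
    else:
        pri = np.array([priors[sp] for sp in species], dtype=float)
        pri = pri / pri.sum()

    pred_orig = np.array([
        _mahalanobis_assign(xi, means, cov, pri, species) for xi in x
    ])

    pred_cv = []
    skipped = []
    keep = np.ones(len(x), dtype=bool)
    for i in range(len(x)):
        if (labels == labels[i]).sum() - 1 < 2:
            skipped.append(str(sub.iloc[i].get("specimen_id", i)))
            pred_cv.append(None)
            continue
        keep[:] = True
        keep[i] = False
        sp_i, means_i, cov_i = _fit_rule_arrays(x[keep], labels[keep])
        pri_i = (np.full(len(sp_i), 1.0 / len(sp_i)) if priors is None
                 else np.array([priors[sp] for sp in sp_i]) /
                 sum(priors[sp] for sp in sp_i))
        pred_cv.append(_mahalanobis_assign(x[i], means_i, cov_i, pri_i, sp_i))

    def table(pred):
        counts = pd.DataFrame(0, index=pd.Index(species, name="species"),
                              columns=species, dtype=int)
        for true, p in zip(labels, pred):
            if p is not None:
                counts.loc[true, p] += 1
        row_tot = counts.sum(axis=1)
        pct = counts.div(row_tot.replace(0, np.nan), axis=0) * 100.0
        correct = np.trace(counts.to_numpy())
        overall = 100.0 * correct / max(1, counts.to_numpy().sum())
        return counts, pct, overall

    counts_o, pct_o, overall_o = table(pred_orig)
    counts_c, pct_c, overall_c = table(pred_cv)

    model = fit_canonical(sub, selected, priors=priors,
                          structure_variables=selected)
    scores = model.scores(sub)
    per_specimen = pd.DataFrame({
        "species": labels,
        "predicted": pred_orig,
        "predicted_cv": [p if p is not None else "" for p in pred_cv],
    })
    if "specimen_id" in sub.columns:
        per_specimen.insert(0, "specimen_id", sub["specimen_id"].to_numpy())
    for j in range(scores.shape[1]):
        per_specimen[f"function{j + 1}"] = scores[:, j]

    return ClassificationTable(
        species=species,
        counts_original=counts_o, counts_cv=counts_c,
        percent_original=pct_o, percent_cv=pct_c,
        overall_original=overall_o, overall_cv=overall_c,
        skipped_folds=skipped,
    ), per_specimen
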