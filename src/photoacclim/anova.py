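"""Treatment inference: mixed models, AICc selection, ANOVA tables, Tukey.

Responses measured repeatedly on the same tree (e.g. across leaf
temperatures) are modelled with linear mixed models carrying a random
intercept per tree; derived parameters with one value per tree fall back to
ordinary least squares.  Fixed-effect structures are chosen by AICc over all
marginality-respecting sub-models of the requested factorial (interactions
enter only with their main effects), fit by maximum likelihood; the chosen
model is refit by REML for reporting.  Per-term F tests use a
between-within (containment-style) split of the denominator degrees of
freedom, and Tukey post-hoc comparisons across the six treatment cells are
reported with a compact letter display.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ModelSpec",
    "SelectionResult",
    "AnovaTable",
    "aicc",
    "candidate_term_sets",
    "select_fixed_effects",
    "repeated_measures_anova",
    "tukey_posthoc",
    "compact_letter_display",
]

Term = tuple[str, ...]  # sorted tuple of factor names, e.g. ("co2_growth", "t_growth")


class UndefinedAICcError(ValueError):
    """AICc is undefined when n <= k + 1."""


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike Information Criterion corrected for small samples.

    AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1); tends to AIC as n grows.
    """
    if n <= k + 1:
        raise UndefinedAICcError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


@dataclass(frozen=True)
class ModelSpec:
    """Candidate fixed-effect structure for one response.

    ``factors`` are candidate main effects; interactions up to ``max_order``
    among them are candidates too, subject to marginality.  ``continuous``
    names factors entered as numeric covariates (all others are treated as
    categorical).  ``always_keep`` terms (e.g. a species blocking factor)
    appear in every candidate.  ``group`` is the random-intercept grouping
    column, or None for a purely fixed-effects analysis.
    """

    response: str
    factors: tuple[str, ...]
    continuous: tuple[str, ...] = ()
    group: str | None = "tree_id"
    max_order: int = 3
    always_keep: tuple[str, ...] = ()


@dataclass(frozen=True)
class SelectionResult:
    terms: tuple[Term, ...]
    ladder: pd.DataFrame  # one row per candidate: terms, k, loglik, aicc
    formula: str


@dataclass(frozen=True)
class AnovaTable:
    """Per-term F/p from the reporting model; dropped terms appear as absent."""

    table: pd.DataFrame  # index: term label; columns: F, p, num_df, den_df, included
    method: str  # "mixed" or "ols"
    formula: str


def _term_label(term: Term) -> str:
    return ":".join(term)


def _term_code(term: Term, continuous: tuple[str, ...]) -> str:
    parts = [f if f in continuous else f"C({f})" for f in term]
    return ":".join(parts)


def _build_formula(response: str, terms: tuple[Term, ...], continuous) -> str:
    if not terms:
        return f"{response} ~ 1"
    rhs = " + ".join(_term_code(t, continuous) for t in terms)
    return f"{response} ~ {rhs}"


def candidate_term_sets(spec: ModelSpec) -> list[tuple[Term, ...]]:
    """All marginality-respecting subsets of the factorial term lattice.

    A subset is admissible when every interaction it contains also has all
    of its lower-order relatives present.  Returned in a canonical order
    (independent of the order factors were supplied).
    """
    factors = tuple(sorted(spec.factors))
    terms: list[Term] = []
    for order in range(1, min(spec.max_order, len(factors)) + 1):
        for combo in itertools.combinations(factors, order):
            terms.append(tuple(sorted(combo)))
    keep = tuple(tuple(sorted((t,) if isinstance(t, str) else t)) for t in spec.always_keep)

    admissible = []
    for mask in range(2 ** len(terms)):
        chosen = frozenset(terms[i] for i in range(len(terms)) if mask >> i & 1)
        if not all(k in chosen for k in keep):
            continue
        ok = True
        for t in chosen:
            if len(t) > 1:
                for order in range(1, len(t)):
                    for sub in itertools.combinations(t, order):
                        if tuple(sorted(sub)) not in chosen:
                            ok = False
                            break
                    if not ok:
                        break
            if not ok:
                break
        if ok:
            admissible.append(tuple(sorted(chosen, key=lambda t: (len(t), t))))
    admissible.sort(key=lambda ts: (len(ts), ts))
    return admissible


def _fit_model(data, formula, group, reml):
    """Fit mixed (if grouped with replication) or OLS; return (result, method, k)."""
    use_mixed = False
    if group is not None and group in data.columns:
        counts = data.groupby(group).size()
        use_mixed = len(counts) < len(data) and len(counts) > 1
    if use_mixed:
        model = smf.mixedlm(formula, data=data, groups=data[group])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                result = model.fit(reml=reml)
            except np.linalg.LinAlgError:
                result = model.fit(reml=reml, method="powell")
        singular = not np.isfinite(result.cov_re.iloc[0, 0]) or (
            result.cov_re.iloc[0, 0] <= 1e-10 * max(result.scale, 1e-12)
        )
        if singular:
            warnings.warn(
                "random-intercept variance is singular; refitting as a "
                "fixed-effects model",
                stacklevel=2,
            )
        else:
            k = len(result.fe_params) + 2  # + residual and random-intercept variances
            return result, "mixed", k
    result = smf.ols(formula, data=data).fit()
    k = int(result.df_model) + 1 + 1  # mean params incl intercept + residual variance
    return result, "ols", k


def select_fixed_effects(data: pd.DataFrame, spec: ModelSpec) -> SelectionResult:
    """Minimum-AICc fixed-effect structure among hierarchical candidates.

    Candidates are fit by maximum likelihood; ties are broken toward fewer
    parameters (then canonical term order), so the choice does not depend on
    the order candidates are generated.
    """
    candidates = candidate_term_sets(spec)
    if len(candidates) < 1:
        raise ValueError("no candidate structures")
    rows = []
    failures = []
    for terms in candidates:
        formula = _build_formula(spec.response, terms, spec.continuous)
        try:
            result, method, k = _fit_model(data, formula, spec.group, reml=False)
            value = aicc(float(result.llf), k, len(data))
        except UndefinedAICcError as exc:
            failures.append((formula, str(exc)))
            continue
        except Exception as exc:  # non-convergence: excluded with a logged reason
            failures.append((formula, repr(exc)))
            continue
        rows.append(
            {
                "terms": " + ".join(_term_label(t) for t in terms) or "1",
                "n_terms": len(terms),
                "k": k,
                "loglik": float(result.llf),
                "aicc": value,
                "_terms": terms,
            }
        )
    if not rows:
        raise RuntimeError(f"all candidate fits failed: {failures}")
    ladder = pd.DataFrame(rows).sort_values(
        by=["aicc", "k", "terms"], kind="mergesort"
    )
    best_terms = ladder.iloc[0]["_terms"]
    ladder = ladder.drop(columns="_terms").reset_index(drop=True)
    return SelectionResult(
        terms=best_terms,
        ladder=ladder,
        formula=_build_formula(spec.response, best_terms, spec.continuous),
    )


def _between_within_ddf(X, groups, term_slices):
    """Containment-style denominator df split.

    A term is between-subject when its design columns are constant within
    every group; its F test is referred to (n_groups - rank of the
    group-mean design).  Within-subject terms use
    (n_obs - n_groups - n_within_params).
    """
    df_groups = pd.DataFrame(X)
    df_groups["_g"] = np.asarray(groups)
    gmeans = df_groups.groupby("_g").mean()
    rank_b = np.linalg.matrix_rank(gmeans.values)
    rank_x = np.linalg.matrix_rank(X)
    n_groups = gmeans.shape[0]
    n_obs = X.shape[0]
    ddf_between = max(n_groups - rank_b, 1)
    ddf_within = max(n_obs - n_groups - (rank_x - rank_b), 1)

    is_between = {}
    within_var = df_groups.groupby("_g").var(ddof=0)
    for label, sl in term_slices.items():
        cols = list(range(sl.start, sl.stop))
        is_between[label] = bool(
            np.all(within_var.iloc[:, cols].values < 1e-10)
        )
    return is_between, ddf_between, ddf_within


def repeated_measures_anova(
    data: pd.DataFrame,
    spec: ModelSpec,
    terms: tuple[Term, ...] | None = None,
) -> AnovaTable:
    """Per-term F and p values from the reporting (REML) model.

    ``terms`` is the chosen fixed-effect structure (e.g. from
    :func:`select_fixed_effects`); None means the full factorial.  Candidate
    terms absent from the structure are reported with blank F/p and
    ``included=False``, mirroring an all-candidates summary table.
    """
    all_terms = candidate_term_sets(spec)[-1]  # the full factorial
    if terms is None:
        terms = all_terms
    formula = _build_formula(spec.response, terms, spec.continuous)
    result, method, _ = _fit_model(data, formula, spec.group, reml=True)

    y, X = patsy.dmatrices(formula, data, return_type="dataframe")
    di = X.design_info
    term_slices = {
        t.name(): di.term_name_slices[t.name()]
        for t in di.terms
        if t.name() != "Intercept"
    }

    if method == "mixed":
        params = np.asarray(result.fe_params)
        cov = np.asarray(result.cov_params())[: len(params), : len(params)]
        is_between, ddf_b, ddf_w = _between_within_ddf(
            X.values, data[spec.group], term_slices
        )
    else:
        params = np.asarray(result.params)
        cov = np.asarray(result.cov_params())
        is_between = {label: True for label in term_slices}
        ddf_b = ddf_w = int(result.df_resid)

    rows = {}
    for term in terms:
        code = _term_code(term, spec.continuous)
        label = _patsy_term_name(code, di)
        sl = term_slices[label]
        L = np.zeros((sl.stop - sl.start, len(params)))
        for i, col in enumerate(range(sl.start, sl.stop)):
            L[i, col] = 1.0
        q = np.linalg.matrix_rank(L)
        lb = L @ params
        lvl = L @ cov @ L.T
        # degenerate responses (zero residual variance) give a 0/0 Wald ratio
        if np.max(np.abs(lb)) < 1e-10 and np.max(np.abs(lvl)) < 1e-10:
            f_stat = 0.0
        else:
            f_stat = float(lb @ np.linalg.solve(lvl, lb) / q)
        ddf = ddf_b if is_between[label] else ddf_w
        p = float(sps.f.sf(f_stat, q, ddf))
        rows[_term_label(term)] = {
            "F": f_stat,
            "p": p,
            "num_df": q,
            "den_df": ddf,
            "included": True,
        }
    for term in all_terms:
        label = _term_label(term)
        if label not in rows:
            rows[label] = {
                "F": np.nan,
                "p": np.nan,
                "num_df": np.nan,
                "den_df": np.nan,
                "included": False,
            }
    order = [_term_label(t) for t in all_terms]
    table = pd.DataFrame(rows).T.loc[order]
    return AnovaTable(table=table, method=method, formula=formula)


def _patsy_term_name(code: str, design_info) -> str:
    """Match our term code to patsy's canonical term name (factor order may differ)."""
    want = set(code.split(":"))
    for t in design_info.terms:
        name = t.name()
        if name == "Intercept":
            continue
        if set(name.split(":")) == want:
            return name
    raise KeyError(f"term {code!r} not in design {design_info.term_names}")


# ---------------------------------------------------------------------------
# Tukey post-hoc comparisons and compact letter display
# ---------------------------------------------------------------------------


def tukey_posthoc(
    data: pd.DataFrame,
    response: str,
    between: tuple[str, str] = ("t_growth", "co2_growth"),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """All pairwise studentized-range comparisons across treatment cells.

    Cells are the crossing of ``between`` (six cells in the reference
    design, hence 15 comparisons).  Returns the pairwise table with adjusted
    p values and a compact letter display; cells sharing no letter differ at
    the given alpha.
    """
    cells = data[list(between)].astype(str).agg("-".join, axis=1)
    if cells.nunique() < 2:
        raise ValueError("need at least 2 treatment cells")
    res = pairwise_tukeyhsd(
        endog=np.asarray(data[response], dtype=float),
        groups=np.asarray(cells),
        alpha=alpha,
    )
    pairs = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    pairs["p-adj"] = np.asarray(res.pvalues, dtype=float)
    means = data.groupby(cells)[response].mean()
    sig = {
        (str(a), str(b)): bool(r)
        for a, b, r in zip(pairs["group1"], pairs["group2"], res.reject)
    }
    letters = compact_letter_display(list(means.sort_values(ascending=False).index), sig)
    return pairs, letters


def compact_letter_display(
    groups_by_mean: list[str], significant: dict[tuple[str, str], bool]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant[(a, b)]`` marks pairs that differ; unordered lookup is
    handled internally.  Groups sharing at least one letter are not
    significantly different; groups sharing none are.
    """

    def differs(a, b):
        return significant.get((a, b), significant.get((b, a), False))

    letter_sets: list[set[str]] = [set(groups_by_mean)]
    for a, b in itertools.combinations(groups_by_mean, 2):
        if not differs(a, b):
            continue
        for s in [s for s in letter_sets if a in s and b in s]:
            letter_sets.remove(s)
            sa, sb = s - {b}, s - {a}
            for new in (sa, sb):
                if not any(new <= other for other in letter_sets):
                    letter_sets.append(new)
    # absorb duplicates/subsets, keep deterministic order by best group rank
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < other or (s == other and j < i)
                   for j, other in enumerate(letter_sets) if j != i)
    ]
    letter_sets.sort(key=lambda s: min(groups_by_mean.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups_by_mean}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups_by_mean:
            if g in s:
                out[g] += letter
    return out
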