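"""Seasonal and inter-specific inference.

Recovery of normalized water use after rehydration, per-species seasonal
minimum water potentials, AIC-based model selection with likelihood-ratio
confirmation, one-way ANOVA with Tukey HSD and compact letter display, and
stomatal-conductance / water-potential envelopes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, DomainError, InvalidConfigError

__all__ = [
    "PsiObservation",
    "RecoveryResult",
    "ModelCandidate",
    "recovery_metric",
    "min_water_potentials",
    "fit_ols_candidates",
    "compare_models_aic",
    "anova_tukey",
    "compact_letter_display",
    "gs_psi_envelope",
]

DEFAULT_PSI_TOLERANCE_MPA = 0.1


@dataclass(frozen=True)
class PsiObservation:
    """One predawn or midday water-potential measurement."""

    date: pd.Timestamp
    individual_id: str
    species: str
    period: Literal["predawn", "midday"]
    psi: float  # MPa

    def __post_init__(self) -> None:
        if self.psi > 0:
            raise DomainError("psi must be <= 0 MPa")
        if self.period not in ("predawn", "midday"):
            raise DomainError(f"unknown period {self.period!r}")


@dataclass
class RecoveryResult:
    """Post-rehydration recovery of a normalized daily quantity."""

    species: str
    season: str
    quantity: str
    recovery_percent: float | None  # % of reference, None if no rehydration
    trigger_date: pd.Timestamp | None

    @property
    def rehydrated(self) -> bool:
        return self.trigger_date is not None


@dataclass(frozen=True)
class ModelCandidate:
    """A fitted candidate in the AIC-selection workflow."""

    label: str
    fixed_terms: tuple
    interaction_terms: tuple
    loglik: float
    k: int  # parameter count

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    def is_nested_in(self, other: "ModelCandidate") -> bool:
        """True if this candidate's terms are a subset of ``other``'s."""
        return (
            set(self.fixed_terms) <= set(other.fixed_terms)
            and set(self.interaction_terms) <= set(other.interaction_terms)
            and self.k <= other.k
        )


def recovery_metric(
    normalized: pd.Series,
    predawn: pd.Series,
    reference_predawn: float,
    tolerance: float = DEFAULT_PSI_TOLERANCE_MPA,
    species: str = "",
    season: str = "",
    quantity: str = "",
) -> RecoveryResult:
    """Maximum % recovery after predawn psi returns to pre-stressed values.

    ``normalized`` is a daily percent-of-reference series; ``predawn`` is a
    daily mean predawn-psi series (MPa).  The trigger date is the first date
    after the seasonal psi minimum where predawn >= reference - tolerance;
    recovery is the maximum normalized value on or after that date.  Absence
    of rehydration is flagged (result with None fields), not an exception.
    """
    normalized = normalized.sort_index().dropna()
    predawn = predawn.sort_index().dropna()
    if predawn.empty or normalized.empty:
        return RecoveryResult(species, season, quantity, None, None)
    min_date = predawn.idxmin()
    after = predawn.loc[predawn.index > min_date]
    qualifying = after.loc[after >= reference_predawn - tolerance]
    if qualifying.empty:
        return RecoveryResult(species, season, quantity, None, None)
    trigger = qualifying.index[0]
    window = normalized.loc[normalized.index >= trigger]
    if window.empty:
        return RecoveryResult(species, season, quantity, None, trigger)
    return RecoveryResult(
        species, season, quantity, float(window.max()), trigger
    )


def min_water_potentials(observations: Sequence[PsiObservation] | pd.DataFrame) -> pd.DataFrame:
    """Seasonal minima: most negative per-date species mean, with that date's SE.

    Input observations need ``date``, ``species``, ``period``, ``psi`` and
    optionally ``season`` fields.  Output rows: species x season x period
    with the minimum of per-date means, its SE over that date's individuals,
    the date and sample size.
    """
    if isinstance(observations, pd.DataFrame):
        df = observations.copy()
    else:
        df = pd.DataFrame(
            {
                "date": [o.date for o in observations],
                "species": [o.species for o in observations],
                "period": [o.period for o in observations],
                "psi": [o.psi for o in observations],
            }
        )
    if df.empty:
        return pd.DataFrame(
            columns=["species", "season", "period", "psi_min", "se", "date", "n"]
        )
    if "season" not in df:
        df["season"] = "all"
    rows = []
    for (species, season, period), grp in df.groupby(
        ["species", "season", "period"], sort=True
    ):
        by_date = grp.groupby("date")["psi"]
        means = by_date.mean()
        min_date = means.idxmin()
        at_min = grp.loc[grp["date"] == min_date, "psi"]
        n = len(at_min)
        se = float(at_min.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append(
            {
                "species": species,
                "season": season,
                "period": period,
                "psi_min": float(means.loc[min_date]),
                "se": se,
                "date": min_date,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model selection


def fit_ols_candidates(
    data: pd.DataFrame,
    response: str,
    candidate_formulas: Sequence[tuple[str, str]],
) -> list[ModelCandidate]:
    """Fit a set of OLS candidates by formula on identical data.

    ``candidate_formulas`` is a list of (label, patsy formula RHS); the
    ModelCandidate records the fixed main-effect and interaction terms
    parsed from the formula.
    """
    import statsmodels.formula.api as smf

    out = []
    for label, rhs in candidate_formulas:
        fit = smf.ols(f"{response} ~ {rhs}", data=data).fit()
        terms = [t.strip() for t in rhs.split("+")]
        fixed = tuple(t for t in terms if ":" not in t and "*" not in t and t != "1")
        inter = tuple(t for t in terms if ":" in t or "*" in t)
        # expand a*b shorthand into its main effects as well
        expanded_fixed = set(fixed)
        for t in inter:
            for part in t.replace("*", ":").split(":"):
                expanded_fixed.add(part.strip())
        out.append(
            ModelCandidate(
                label=label,
                fixed_terms=tuple(sorted(expanded_fixed)),
                interaction_terms=tuple(sorted(inter)),
                loglik=float(fit.llf),
                k=int(fit.df_model) + 2,  # coefficients + intercept + sigma
            )
        )
    return out


def likelihood_ratio_p(reduced: ModelCandidate, full: ModelCandidate) -> float:
    """Chi-square p-value for a nested likelihood-ratio comparison."""
    if not reduced.is_nested_in(full):
        raise InvalidConfigError("likelihood ratio requires nested models")
    stat = 2.0 * (full.loglik - reduced.loglik)
    df = full.k - reduced.k
    if df <= 0:
        return 1.0
    return float(stats.chi2.sf(max(stat, 0.0), df))


def compare_models_aic(
    candidates: Sequence[ModelCandidate], alpha: float = 0.05
) -> ModelCandidate:
    """Select the lowest-AIC candidate that beats its nested rivals.

    Starting from the lowest-AIC candidate (ties broken by fewer
    parameters), any nested simpler candidate whose likelihood-ratio test
    against the current choice is non-significant (p >= alpha) replaces it —
    the extra terms are not supported.  Non-nested rivals cannot be tested
    by likelihood ratio and are ranked by AIC alone.
    """
    if len(candidates) < 2:
        raise InvalidConfigError("need >= 2 candidates")
    current = min(candidates, key=lambda c: (c.aic, c.k))
    changed = True
    while changed:
        changed = False
        simpler = [
            c
            for c in candidates
            if c is not current and c.k < current.k and c.is_nested_in(current)
        ]
        for cand in sorted(simpler, key=lambda c: (c.aic, c.k)):
            if likelihood_ratio_p(cand, current) >= alpha:
                current = cand
                changed = True
                break
    # identical-structure tie: prefer fewer parameters
    for cand in candidates:
        if (
            cand is not current
            and cand.k < current.k
            and np.isclose(cand.aic, current.aic)
            and np.isclose(cand.loglik, current.loglik)
        ):
            current = cand
    return current


# ---------------------------------------------------------------------------
# ANOVA + Tukey


def compact_letter_display(
    groups: Sequence[str],
    significant_pairs: set[tuple[str, str]],
    means: dict[str, float],
) -> dict[str, str]:
    """Compact letters: groups sharing no letter differ significantly.

    Letters are the maximal cliques of the non-significance graph, labelled
    in order of decreasing group mean.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(groups)
    for x, y in itertools.combinations(groups, 2):
        if (x, y) not in significant_pairs and (y, x) not in significant_pairs:
            g.add_edge(x, y)
    cliques = list(nx.find_cliques(g))
    # stable ordering: cliques by the largest member mean, descending
    cliques.sort(key=lambda c: -max(means[m] for m in c))
    letters = {grp: "" for grp in groups}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for member in sorted(clique, key=lambda m: -means[m]):
            letters[member] += letter
    return {grp: "".join(sorted(v)) for grp, v in letters.items()}


def anova_tukey(
    values: Sequence[float] | pd.Series,
    groups: Sequence[str],
    alpha: float = 0.05,
) -> dict:
    """One-way ANOVA with Tukey HSD post hoc and compact letter display.

    Returns a dict with F, df (between, within), p, the Tukey results table
    and per-group letters.  Requires >= 2 groups with >= 2 values each.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise DegenerateFitError("need >= 2 groups")
    if np.any(counts < 2):
        small = labels[counts < 2].tolist()
        raise DegenerateFitError(f"groups with a single value: {small}")
    samples = [values[groups == lab] for lab in labels]
    f_stat, p_value = stats.f_oneway(*samples)
    df_between = len(labels) - 1
    df_within = len(values) - len(labels)

    tukey = pairwise_tukeyhsd(values, groups, alpha=alpha)
    table = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    significant = {
        (str(r["group1"]), str(r["group2"]))
        for _, r in table.iterrows()
        if bool(r["reject"])
    }
    means = {str(lab): float(np.mean(values[groups == lab])) for lab in labels}
    letters = compact_letter_display([str(x) for x in labels], significant, means)
    return {
        "F": float(f_stat),
        "df": (df_between, df_within),
        "p": float(p_value),
        "tukey": table,
        "letters": letters,
    }


# ---------------------------------------------------------------------------
# gs-psi envelopes


def gs_psi_envelope(
    gs_obs: pd.DataFrame,
    psi_obs: pd.DataFrame,
    closure_fraction: float = 0.10,
) -> dict:
    """Pair stomatal conductance with midday psi by species and date.

    Returns the paired envelope table plus, per species, the water potential
    at which gs falls below ``closure_fraction`` of its maximum (linear
    interpolation along the psi-sorted envelope); flagged None when gs never
    drops below the closure level.
    """
    psi_midday = psi_obs.loc[psi_obs["period"] == "midday"] if "period" in psi_obs else psi_obs
    psi_daily = (
        psi_midday.groupby(["species", "date"], as_index=False)["psi"].mean()
    )
    merged = gs_obs.merge(psi_daily, on=["species", "date"], how="inner")
    closure: dict[str, float | None] = {}
    if merged.empty:
        import warnings

        warnings.warn("no overlapping species/date pairs between gs and psi")
        return {"points": merged, "closure_psi": closure}
    for species, grp in merged.groupby("species"):
        gs_max = grp["gs"].max()
        if gs_max <= 0 or grp["gs"].nunique() == 1:
            closure[species] = None
            continue
        level = closure_fraction * gs_max
        pts = grp.sort_values("psi")  # most negative first
        below = pts["gs"] <= level
        if not below.any():
            closure[species] = None
            continue
        # psi where gs first crosses the closure level, scanning wet -> dry
        psi_sorted = pts["psi"].to_numpy()[::-1]
        gs_sorted = pts["gs"].to_numpy()[::-1]
        crossing = None
        for i in range(1, len(gs_sorted)):
            if gs_sorted[i] <= level < gs_sorted[i - 1]:
                frac = (gs_sorted[i - 1] - level) / (gs_sorted[i - 1] - gs_sorted[i])
                crossing = psi_sorted[i - 1] + frac * (psi_sorted[i] - psi_sorted[i - 1])
                break
        if crossing is None and gs_sorted[0] <= level:
            crossing = psi_sorted[0]
        closure[species] = float(crossing) if crossing is not None else None
    return {"points": merged, "closure_psi": closure}
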