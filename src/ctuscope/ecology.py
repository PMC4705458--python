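"""Clade ecology statistics on clade x sample abundance tables.

Counts are aggregated to a chosen rank and converted to relative abundances,
summarized per sample category with min-max scalings, screened for
site-group associations with a one-sided permutation test, and correlated
with numeric environmental variables via Spearman rank correlation with
pairwise deletion of missing values.
"""
from __future__ import annotations

import warnings
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import EnvTable, SampleTable

UNCLASSIFIED = "unclassified"


@dataclass
class AbundanceTable:
    """Relative abundances (samples x clades) at one rank."""

    fractions: pd.DataFrame
    rank: str
    totals: pd.Series  # total reads per sample (classified + unclassified)
    unclassified_fraction: pd.Series

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def clade_ids(self) -> list[str]:
        return list(self.fractions.columns)


@dataclass(frozen=True)
class AssociationResult:
    clade: str
    category: str
    statistic: float
    n_perm: int
    p_value: float
    seed: int


@dataclass(frozen=True)
class CorrelationResult:
    clade: str
    variable: str
    rho: float
    p_value: float
    n_pairs: int
    reported: bool


def aggregate_relative_abundance(
    sample_table: SampleTable,
    lineage_map: Mapping[str, Mapping[str, str] | str],
    rank: str,
) -> AbundanceTable:
    """Sum counts into rank-level clades and normalize per sample.

    ``lineage_map`` sends each count-table clade id either to a
    rank -> name mapping or to the string "unclassified".  Fractions use
    the sample's full read total as denominator, so unclassified mass
    dilutes every clade; it is also reported separately.  Samples with
    zero reads are excluded with a warning.
    """
    target: dict[str, str] = {}
    for clade in sample_table.clade_ids:
        if clade not in lineage_map:
            raise KeyError(f"count-table clade {clade!r} has no lineage")
        lineage = lineage_map[clade]
        if isinstance(lineage, str):
            if lineage != UNCLASSIFIED:
                raise ValueError(
                    f"lineage for {clade!r} must be a mapping or 'unclassified'"
                )
            target[clade] = UNCLASSIFIED
        else:
            target[clade] = lineage[rank]

    counts = sample_table.counts
    grouped = counts.T.groupby(
        pd.Series({c: target[c] for c in counts.columns})
    ).sum().T
    unclassified = (
        grouped.pop(UNCLASSIFIED)
        if UNCLASSIFIED in grouped.columns
        else pd.Series(0, index=grouped.index)
    )
    # denominator is the sample's full read total; unclassified mass dilutes
    totals = grouped.sum(axis=1) + unclassified
    empty = totals[totals == 0].index
    if len(empty):
        warnings.warn(
            f"{len(empty)} samples with zero reads excluded "
            f"(first: {empty[0]!r})",
            stacklevel=2,
        )
        grouped = grouped.drop(index=empty)
        unclassified = unclassified.drop(index=empty)
        totals = totals.drop(index=empty)
    fractions = grouped.div(totals, axis=0)
    return AbundanceTable(
        fractions=fractions,
        rank=rank,
        totals=totals,
        unclassified_fraction=unclassified / totals,
    )


def scaled_summary(
    abundance: AbundanceTable,
    groups: pd.Series,
    scope: str = "all",
    phylum_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Mean relative abundance per (clade, category), min-max scaled.

    ``scope="all"`` scales each clade row over its category means;
    ``scope="per_phylum"`` pools all clades of a phylum and scales within
    that block, so one phylum's values never influence another's.  Constant
    pools map to 0.  Categories without samples are omitted.
    """
    groups = groups.reindex(abundance.fractions.index).dropna()
    means = (
        abundance.fractions.loc[groups.index]
        .groupby(groups)
        .mean()
        .T.sort_index()
    )  # clades x categories
    means = means[[c for c in means.columns if groups.eq(c).any()]]

    def _scale(block: pd.DataFrame) -> pd.DataFrame:
        lo, hi = block.to_numpy().min(), block.to_numpy().max()
        if hi - lo == 0:
            return block * 0.0
        return (block - lo) / (hi - lo)

    if scope == "all":
        return pd.concat(
            [_scale(means.loc[[clade]]) for clade in means.index]
        )
    if scope == "per_phylum":
        if phylum_of is None:
            phylum_of = {c: c.split(".", 1)[0] for c in means.index}
        blocks = {}
        for clade in means.index:
            blocks.setdefault(phylum_of[clade], []).append(clade)
        out = [
            _scale(means.loc[sorted(members)]) for _, members in sorted(blocks.items())
        ]
        return pd.concat(out).loc[means.index]
    raise ValueError(f"unknown scope {scope!r}")


def site_association_test(
    abundance: AbundanceTable,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
    statistic: str = "mean_diff",
) -> list[AssociationResult]:
    """One-sided permutation test of higher abundance in a target category.

    For every (clade, category) pair the observed statistic is the mean
    relative abundance inside the category minus the mean outside
    (``statistic="indval"`` instead uses sqrt(specificity x fidelity)).
    The null is built from ``n_perm`` random permutations of the category
    labels drawn from a generator seeded with ``seed``, and the one-sided
    p-value is (1 + #{permuted >= observed}) / (n_perm + 1).
    """
    groups = groups.reindex(abundance.fractions.index)
    if groups.isna().any():
        raise ValueError("every sample needs a category for the association test")
    categories = sorted(groups.unique())
    if len(categories) < 2:
        raise ValueError("need at least 2 categories")
    x = abundance.fractions.to_numpy(dtype=float)
    n_samples, n_clades = x.shape
    labels = groups.to_numpy()

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n_samples) for _ in range(n_perm)])

    results: list[AssociationResult] = []
    for category in categories:
        mask = (labels == category).astype(float)
        n_in = mask.sum()
        n_out = n_samples - n_in

        def stat_for(indicator: np.ndarray) -> np.ndarray:
            mean_in = indicator @ x / n_in
            if statistic == "mean_diff":
                mean_out = (1.0 - indicator) @ x / n_out
                return mean_in - mean_out
            if statistic == "indval":
                other = (1.0 - indicator) @ x / n_out
                denom = mean_in + other
                specificity = np.divide(
                    mean_in, denom, out=np.zeros_like(mean_in), where=denom > 0
                )
                fidelity = indicator @ (x > 0) / n_in
                return np.sqrt(specificity * fidelity)
            raise ValueError(f"unknown statistic {statistic!r}")

        observed = stat_for(mask)
        null = np.stack([stat_for(mask[p]) for p in perms])
        exceed = (null >= observed[None, :]).sum(axis=0)
        p_values = (1.0 + exceed) / (n_perm + 1.0)
        for k, clade in enumerate(abundance.clade_ids):
            results.append(
                AssociationResult(
                    clade=clade,
                    category=category,
                    statistic=float(observed[k]),
                    n_perm=n_perm,
                    p_value=float(p_values[k]),
                    seed=seed,
                )
            )
    return results


def best_associations(results: list[AssociationResult]) -> dict[str, AssociationResult]:
    """Per clade, the category with the smallest p (ties: larger statistic)."""
    best: dict[str, AssociationResult] = {}
    for r in results:
        cur = best.get(r.clade)
        if (
            cur is None
            or r.p_value < cur.p_value
            or (r.p_value == cur.p_value and r.statistic > cur.statistic)
        ):
            best[r.clade] = r
    return best


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running = 1.0
    for rank_pos in range(n - 1, -1, -1):
        idx = order[rank_pos]
        running = min(running, p[idx] * n / (rank_pos + 1))
        adjusted[idx] = running
    return adjusted


def spearman_screen(
    abundance: AbundanceTable,
    env_table: EnvTable,
    alpha: float = 0.05,
    adjust: str = "none",
) -> list[CorrelationResult]:
    """Spearman correlations of clades vs numeric environment variables.

    Missing values are dropped pairwise; pairs with fewer than 3 complete
    observations or zero variance on either side are skipped.  Results with
    p < alpha (optionally Benjamini-Hochberg adjusted) are flagged reported.
    """
    env = env_table.numeric().reindex(abundance.fractions.index)
    raw: list[CorrelationResult] = []
    for variable in env.columns:
        v = env[variable]
        for clade in abundance.clade_ids:
            a = abundance.fractions[clade]
            ok = a.notna() & v.notna()
            n = int(ok.sum())
            if n < 3:
                continue
            av, vv = a[ok].to_numpy(), v[ok].to_numpy()
            if np.ptp(av) == 0 or np.ptp(vv) == 0:
                continue
            rho, p = stats.spearmanr(av, vv)
            raw.append(
                CorrelationResult(
                    clade=clade,
                    variable=variable,
                    rho=float(rho),
                    p_value=float(p),
                    n_pairs=n,
                    reported=False,
                )
            )
    if not raw:
        return raw
    p_values = np.array([r.p_value for r in raw])
    if adjust == "BH":
        p_eval = _benjamini_hochberg(p_values)
    elif adjust == "none":
        p_eval = p_values
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return [
        CorrelationResult(
            clade=r.clade,
            variable=r.variable,
            rho=r.rho,
            p_value=r.p_value,
            n_pairs=r.n_pairs,
            reported=bool(pe < alpha),
        )
        for r, pe in zip(raw, p_eval)
    ]


def lineage_map_from_hierarchy(
    hierarchy, clade_members: Mapping[str, list[str]]
) -> dict[str, Mapping[str, str] | str]:
    """Map count-table clade ids onto recognized lineages by leaf majority.

    Each count-table clade id is associated with the recognized genus-level
    CTU that contains the plurality of its member leaves; ids whose members
    were all dropped upstream map to "unclassified".
    """
    from .model import RANKS

    leaf_lineage: dict[str, dict[str, str]] = {}
    for rank in RANKS:
        for ctu in hierarchy.at(rank):
            for m in ctu.members:
                leaf_lineage.setdefault(m, {})[rank] = ctu.name

    out: dict[str, Mapping[str, str] | str] = {}
    for clade_id, members in clade_members.items():
        tally: dict[tuple, int] = {}
        for m in members:
            lin = leaf_lineage.get(m)
            if lin is not None:
                key = tuple(lin[r] for r in RANKS)
                tally[key] = tally.get(key, 0) + 1
        if not tally:
            out[clade_id] = UNCLASSIFIED
        else:
            best = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            out[clade_id] = dict(zip(RANKS, best))
    return out
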