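"""Treatment-level growth statistics built on fitted EAF estimates.

Covers assemblage mean contrasts (ANOVA + Tukey HSD with a compact letter
display), percent increases and van't Hoff Q10 temperature sensitivities,
per-taxon warming responses (delta-EAF with joint-block bootstrap confidence
intervals), occurrence partitioning of growing taxa across treatments, and
rank-level aggregation with a minimum-representation rule.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core import EafResults

logger = logging.getLogger(__name__)

__all__ = [
    "assemblage_mean_contrast",
    "percent_increase",
    "fold_change",
    "q10",
    "delta_eaf",
    "occurrence_partition",
    "aggregate_by_rank",
    "ContrastResult",
    "OccurrencePartition",
]


# ---------------------------------------------------------------------------
# scalar contrasts
# ---------------------------------------------------------------------------

def percent_increase(mean_treatment: float, mean_control: float) -> float:
    """Percent change of a treatment mean relative to the control mean."""
    if mean_control <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (mean_treatment - mean_control) / mean_control


def fold_change(mean_treatment: float, mean_control: float) -> float:
    if mean_control <= 0:
        raise ValueError("control mean must be positive")
    return mean_treatment / mean_control


def q10(ratio: float, delta_t: float = 1.6) -> float:
    """van't Hoff Q10: fold change per 10 degrees C from a rate ratio.

    ``ratio`` is the treatment:control rate ratio observed across a warming of
    ``delta_t`` degrees C; ``Q10 = ratio ** (10 / delta_t)``.
    """
    if ratio <= 0 or delta_t <= 0:
        raise ValueError("ratio and delta_t must be positive")
    return float(ratio ** (10.0 / delta_t))


# ---------------------------------------------------------------------------
# assemblage means: ANOVA + Tukey HSD + compact letter display
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    """Mean comparison of per-taxon EAF across treatments."""

    means: pd.Series
    sems: pd.Series
    n: pd.Series
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame          # group1, group2, meandiff, p_adj, reject
    letters: dict                # group -> compact letter display

    def summary(self) -> str:
        lines = [f"One-way ANOVA: F = {self.anova_f:.2f}, p = {self.anova_p:.3g}",
                 f"  {'group':<16}{'n':>6}{'mean':>10}{'sem':>10}  letters"]
        for g in self.means.index:
            lines.append(f"  {str(g):<16}{self.n[g]:>6}{self.means[g]:>10.4f}"
                         f"{self.sems[g]:>10.4f}  {self.letters[g]}")
        return "\n".join(lines)


def _compact_letters(groups, different) -> dict:
    """Compact letter display: groups not significantly different share a letter.

    ``different`` is a set of frozensets of group pairs declared different.
    Letters come from maximal cliques of the "not different" graph, ordered by
    the groups they contain.
    """
    groups = list(groups)
    compatible = {
        frozenset(p) for p in itertools.combinations(groups, 2)
        if frozenset(p) not in different
    }
    cliques = []
    for r in range(len(groups), 0, -1):
        for sub in itertools.combinations(groups, r):
            if all(frozenset(p) in compatible
                   for p in itertools.combinations(sub, 2)):
                if not any(set(sub) <= set(c) for c in cliques):
                    cliques.append(sub)
    cliques.sort(key=lambda c: min(groups.index(g) for g in c))
    letters = {g: "" for g in groups}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in clique:
            letters[g] += letter
    return letters


def assemblage_mean_contrast(results, treatments=None, growing_only: bool = True,
                             alpha: float = 0.05) -> ContrastResult:
    """ANOVA + Tukey HSD of per-taxon EAF across treatments.

    The observation unit is the taxon (each growing taxon contributes its
    post-truncation treatment-mean EAF).  With zero-variance groups the ANOVA
    is still computed but flagged with a warning since Tukey's procedure is
    degenerate under exact ties.
    """
    series = _eaf_groups(results, treatments, growing_only)
    if len(series) < 2:
        raise ValueError("need at least 2 treatments")
    for tr, s in series.items():
        if len(s) < 2:
            raise ValueError(f"treatment {tr!r} has fewer than 2 taxa")
        if np.ptp(s.to_numpy()) == 0:
            warnings.warn(f"treatment {tr!r} has zero variance; Tukey HSD is "
                          "degenerate under exact ties", stacklevel=2)
    values = [s.to_numpy() for s in series.values()]
    f_stat, p = stats.f_oneway(*values)
    flat = np.concatenate(values)
    labels = np.concatenate([[str(tr)] * len(v)
                             for tr, v in zip(series, values)])
    if np.ptp(flat) == 0:
        tukey_df = pd.DataFrame(
            [{"group1": str(a), "group2": str(b), "meandiff": 0.0,
              "p_adj": 1.0, "reject": False}
             for a, b in itertools.combinations(series, 2)])
        f_stat, p = 0.0, 1.0
    else:
        with warnings.catch_warnings():
            # zero within-group variance -> infinite studentised range; the
            # degenerate-groups warning above already flags this
            warnings.simplefilter("ignore", RuntimeWarning)
            tk = pairwise_tukeyhsd(flat, labels, alpha=alpha)
        tukey_df = pd.DataFrame(
            tk.summary().data[1:],
            columns=["group1", "group2", "meandiff", "p_adj", "lower",
                     "upper", "reject"],
        )[["group1", "group2", "meandiff", "p_adj", "reject"]]
        tukey_df["reject"] = tukey_df["reject"].astype(bool)
    different = {
        frozenset((str(r.group1), str(r.group2)))
        for r in tukey_df.itertuples() if r.reject
    }
    letters = _compact_letters([str(tr) for tr in series], different)
    return ContrastResult(
        means=pd.Series({tr: s.mean() for tr, s in series.items()}),
        sems=pd.Series({tr: s.sem() if len(s) > 1 else np.nan
                        for tr, s in series.items()}),
        n=pd.Series({tr: len(s) for tr, s in series.items()}),
        anova_f=float(f_stat), anova_p=float(p),
        tukey=tukey_df, letters={tr: letters[str(tr)] for tr in series},
    )


def _eaf_groups(results, treatments, growing_only):
    if isinstance(results, EafResults):
        if treatments is None:
            treatments = results.treatments
        return {tr: results.eaf_series(tr, growing_only=growing_only)
                for tr in treatments}
    # plain mapping of treatment -> Series/array
    return {tr: pd.Series(v) for tr, v in dict(results).items()
            if treatments is None or tr in treatments}


# ---------------------------------------------------------------------------
# per-taxon warming response
# ---------------------------------------------------------------------------

def delta_eaf(results: EafResults, treatment, control="control",
              n_boot: int = 1000, ci_level: float = 0.90,
              seed=None, ci_method: str = "expanded",
              pair_blocks: bool = False) -> pd.DataFrame:
    """Per-taxon growth response ``EAF_treatment - EAF_control`` with bootstrap CI.

    Only taxa growing in both treatments are scored.  Each arm's field blocks
    are resampled with replacement independently (set ``pair_blocks=True`` to
    apply one joint block draw to both arms instead); replicates difference
    the raw (untruncated) arm means over the drawn qualifying blocks, while
    the point estimate differences the reported post-truncation treatment
    means.  Classification: ``positive`` if the CI lower bound exceeds 0,
    ``negative`` if the upper bound is below 0, ``neutral`` otherwise.

    With few field blocks the plain percentile interval is systematically too
    narrow (it misses the usual ``sqrt(B/(B-1))`` and t-versus-normal
    corrections), so the default ``ci_method="expanded"`` reads the bootstrap
    distribution at expanded percentile points chosen so the interval attains
    its nominal level for small ``B``; ``"percentile"`` gives the plain
    interval.
    """
    if treatment == control:
        raise ValueError("treatment and control must differ")
    # one stream per arm, assigned by sorted label so that swapping the roles
    # of treatment and control exactly negates the replicate distribution
    ss = np.random.SeedSequence(seed)
    children = dict(zip(sorted((str(treatment), str(control))), ss.spawn(2)))
    rng_t = np.random.default_rng(children[str(treatment)])
    rng_c = np.random.default_rng(children[str(control)])
    t_tab = results.treatment_table(treatment)
    c_tab = results.treatment_table(control)
    taxa = t_tab.index[t_tab["growing"]].intersection(
        c_tab.index[c_tab["growing"]])
    n_skipped = (len(set(t_tab.index) | set(c_tab.index)) - len(taxa))
    logger.info("delta_eaf %s vs %s: %d taxa scored, %d not growing in both",
                treatment, control, len(taxa), n_skipped)

    blocks = sorted(results.block_table["block"].unique())
    b_index = {b: i for i, b in enumerate(blocks)}

    def pivot(tr):
        sub = results.block_table[results.block_table["treatment"] == tr]
        piv = np.full((len(taxa), len(blocks)), np.nan)
        t_pos = {t: i for i, t in enumerate(taxa)}
        for row in sub.itertuples(index=False):
            if row.taxon_id in t_pos:
                piv[t_pos[row.taxon_id], b_index[row.block]] = row.eaf_raw
        return piv

    piv_t, piv_c = pivot(treatment), pivot(control)
    draws_t = rng_t.integers(0, len(blocks), size=(n_boot, len(blocks)))
    draws_c = draws_t if pair_blocks else rng_c.integers(
        0, len(blocks), size=(n_boot, len(blocks)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_t = np.nanmean(piv_t[:, draws_t], axis=2)
        mean_c = np.nanmean(piv_c[:, draws_c], axis=2)
    reps = mean_t - mean_c          # raw per-block values; no truncation here
    alpha = (1 - ci_level) / 2
    if ci_method == "expanded":
        n_b = len(blocks)
        if n_b >= 2:  # expansion undefined below 2 blocks
            z = stats.t.ppf(1 - alpha, df=n_b - 1) * np.sqrt(n_b / (n_b - 1))
            alpha = float(stats.norm.sf(z))
    elif ci_method != "percentile":
        raise ValueError("ci_method must be 'expanded' or 'percentile'")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ci_lo = np.nanpercentile(reps, 100 * alpha, axis=1)
        ci_hi = np.nanpercentile(reps, 100 * (1 - alpha), axis=1)

    point = (t_tab.loc[taxa, "mean_eaf"] - c_tab.loc[taxa, "mean_eaf"]).to_numpy()
    cls = np.where(ci_lo > 0, "positive",
                   np.where(ci_hi < 0, "negative", "neutral"))
    return pd.DataFrame({
        "taxon_id": taxa, "treatment": treatment, "control": control,
        "delta_eaf": point, "ci_lo": ci_lo, "ci_hi": ci_hi,
        "classification": cls,
    }).set_index("taxon_id")


# ---------------------------------------------------------------------------
# occurrence partitioning
# ---------------------------------------------------------------------------

@dataclass
class OccurrencePartition:
    """Growing taxa partitioned by the set of treatments they grow in."""

    membership: pd.Series        # taxon -> tuple of treatments (sorted)
    counts: pd.Series            # category (tuple) -> n taxa
    category_means: pd.DataFrame  # rows: category; columns: member treatments
    tests: pd.DataFrame          # per multi-treatment category: test, stat, p

    def summary(self) -> str:
        lines = ["Occurrence partition of growing taxa"]
        for cat, n in self.counts.items():
            lines.append(f"  {{{', '.join(map(str, cat))}}}: {n} taxa")
        return "\n".join(lines)


def occurrence_partition(results: EafResults, treatments=None) -> OccurrencePartition:
    """Assign each growing taxon to its treatment-membership category.

    Every growing taxon lands in exactly one of the ``2^k - 1`` non-empty
    membership categories.  Per category, mean EAF is reported for each member
    treatment; categories spanning two treatments are compared with a paired
    Student's t test across taxa, three or more with one-way ANOVA.
    """
    if treatments is None:
        treatments = results.treatments
    if len(treatments) < 2:
        raise ValueError("need at least 2 treatments")
    growing = {tr: set(results.growing_taxa(tr)) for tr in treatments}
    all_growing = sorted(set().union(*growing.values()))
    membership = pd.Series(
        {t: tuple(tr for tr in treatments if t in growing[tr])
         for t in all_growing}
    )
    counts = membership.value_counts().sort_index()

    mean_rows, test_rows = [], []
    for cat in counts.index:
        taxa = membership.index[membership == cat]
        row = {"category": cat, "n": len(taxa)}
        vals = {}
        for tr in cat:
            vals[tr] = results.treatment_table(tr).loc[taxa, "mean_eaf"]
            row[str(tr)] = vals[tr].mean()
        mean_rows.append(row)
        if len(cat) < 2 or len(taxa) < 2:
            continue
        if len(cat) == 2:
            a, b = (vals[tr].to_numpy() for tr in cat)
            t_stat, p = stats.ttest_rel(a, b)
            test_rows.append({"category": cat, "test": "paired t",
                              "stat": float(t_stat), "pvalue": float(p)})
        else:
            f_stat, p = stats.f_oneway(*(vals[tr].to_numpy() for tr in cat))
            test_rows.append({"category": cat, "test": "anova",
                              "stat": float(f_stat), "pvalue": float(p)})
    category_means = pd.DataFrame(mean_rows).set_index("category")
    tests = (pd.DataFrame(test_rows).set_index("category")
             if test_rows else pd.DataFrame(columns=["test", "stat", "pvalue"]))
    return OccurrencePartition(membership=membership, counts=counts,
                               category_means=category_means, tests=tests)


# ---------------------------------------------------------------------------
# rank-level aggregation
# ---------------------------------------------------------------------------

def aggregate_by_rank(results: EafResults, taxonomy: pd.DataFrame, rank: str,
                      treatment=None, control="control",
                      min_taxa: int = 3) -> pd.DataFrame:
    """Group-mean EAF and delta-EAF at a taxonomic rank.

    A group (e.g. an order) is reported only if it has at least ``min_taxa``
    growing representatives in *both* the warming treatment and the control;
    groups failing the rule are omitted (logged).
    """
    if rank not in taxonomy.columns:
        raise KeyError(f"unknown rank label {rank!r}")
    if treatment is None:
        treatment = [tr for tr in results.treatments if tr != control]
        frames = [aggregate_by_rank(results, taxonomy, rank, tr, control,
                                    min_taxa) for tr in treatment]
        return pd.concat(frames, ignore_index=True)

    t_eaf = results.eaf_series(treatment, growing_only=True)
    c_eaf = results.eaf_series(control, growing_only=True)
    rows, omitted = [], 0
    for group, members in taxonomy.groupby(rank).groups.items():
        t_vals = t_eaf.loc[t_eaf.index.intersection(members)]
        c_vals = c_eaf.loc[c_eaf.index.intersection(members)]
        if len(t_vals) < min_taxa or len(c_vals) < min_taxa:
            omitted += 1
            continue
        rows.append({
            "rank": rank, "group": group, "treatment": treatment,
            "control": control, "n_treatment": len(t_vals),
            "n_control": len(c_vals),
            "mean_eaf_treatment": t_vals.mean(),
            "mean_eaf_control": c_vals.mean(),
            "delta_eaf": t_vals.mean() - c_vals.mean(),
        })
    logger.info("aggregate_by_rank %s (%s vs %s): %d groups reported, "
                "%d omitted by min-%d rule", rank, treatment, control,
                len(rows), omitted, min_taxa)
    return pd.DataFrame(rows, columns=[
        "rank", "group", "treatment", "control", "n_treatment", "n_control",
        "mean_eaf_treatment", "mean_eaf_control", "delta_eaf"])
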