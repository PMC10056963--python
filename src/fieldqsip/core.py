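"""Core qSIP calculations: weighted average density and 18O excess atom fraction.

The estimator works on density-gradient fraction data.  For every taxon in
every tube, per-fraction 16S copy numbers are reconstructed from relative
abundance and qPCR totals, a weighted average density (WAD) is computed over
the gradient, and the shift in WAD between paired ``18O`` and ``16O`` tubes is
converted into the excess atom fraction (EAF) of ``18O`` in that taxon's DNA —
a proxy for its relative growth rate during the labeling period.

:class:`EafModel` is the entry point: it is built from a dataset (fraction
metadata plus a taxon x fraction-sample count matrix) and its :meth:`~EafModel.fit`
returns an :class:`EafResults` with per-taxon, per-treatment EAF estimates,
block-level values, bootstrap confidence intervals and growth flags.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    DENSITY_INTERCEPT,
    DENSITY_SLOPE,
    MW_GC_SLOPE,
    MW_INTERCEPT,
    MW_MAX_18O_SHIFT,
    NATURAL_ABUNDANCE_18O,
)

logger = logging.getLogger(__name__)

__all__ = [
    "taxon_copies",
    "weighted_average_density",
    "consecutive_fraction_filter",
    "gc_from_density",
    "molecular_weights",
    "eaf_from_wad_shift",
    "unlabeled_density",
    "labeled_density",
    "EafModel",
    "EafResults",
]


# ---------------------------------------------------------------------------
# elementary conversions
# ---------------------------------------------------------------------------

def taxon_copies(p, totals):
    """Per-fraction 16S copies of one taxon.

    Parameters
    ----------
    p : array-like
        Relative abundance of the taxon in each fraction, in ``[0, 1]``.
    totals : array-like
        Total 16S copies (qPCR) of each fraction.

    Returns
    -------
    ndarray
        ``y_i = p_i * totals_i`` elementwise.
    """
    p = np.asarray(p, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if p.shape != totals.shape:
        raise ValueError(
            f"length mismatch: {p.shape} relative abundances vs {totals.shape} totals"
        )
    if (p < 0).any() or (p > 1 + 1e-9).any():
        raise ValueError("relative abundances must lie in [0, 1]")
    if (totals < 0).any():
        raise ValueError("qPCR totals must be non-negative")
    return p * totals


def weighted_average_density(x, y):
    """Abundance-weighted mean buoyant density of a taxon across fractions.

    ``W = sum(x_i y_i) / sum(y_i)``.  Returns ``nan`` (taxon absent, not an
    error) when the taxon has zero copies everywhere.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s = y.sum()
    if s <= 0:
        return float("nan")
    return float((x * y).sum() / s)


def consecutive_fraction_filter(y, min_run: int = 3) -> bool:
    """True iff the taxon occurs in ``min_run`` or more consecutive fractions.

    "Occurs" means strictly positive copies / abundance.  ``y`` must be ordered
    by fraction index.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    present = np.asarray(y) > 0
    if present.size < min_run:
        return False
    run = 0
    for flag in present:
        run = run + 1 if flag else 0
        if run >= min_run:
            return True
    return False


def _runs_ge(present: np.ndarray, min_run: int) -> np.ndarray:
    """Vectorised consecutive-run filter over rows of a boolean matrix."""
    if present.shape[1] < min_run:
        return np.zeros(present.shape[0], dtype=bool)
    window = np.ones(min_run)
    conv = np.apply_along_axis(
        lambda r: np.convolve(r, window, mode="valid"), 1, present.astype(float)
    )
    return (conv >= min_run - 1e-9).any(axis=1)


def gc_from_density(w_light, warn: bool = True):
    """GC content inferred from the unlabeled weighted average density.

    Inverts the linear density–GC relation; results outside ``[0, 1]`` are
    clamped (with a warning) since densities near the gradient edges can place
    the nominal GC slightly out of range.
    """
    w = np.asarray(w_light, dtype=float)
    g = (w - DENSITY_INTERCEPT) / DENSITY_SLOPE
    out = (g < -1e-9) | (g > 1 + 1e-9)
    if warn and np.any(out & np.isfinite(g)):
        warnings.warn(
            f"{int(np.sum(out & np.isfinite(g)))} GC estimate(s) outside [0, 1]; clamped",
            stacklevel=2,
        )
    g = np.clip(g, 0.0, 1.0)
    return float(g) if np.isscalar(w_light) else g


def molecular_weights(g):
    """Molecular weights (g mol^-1 per average nucleotide) for GC content ``g``.

    Returns ``(M_light, M_heavymax)``: unlabeled, and fully 18O-labeled.
    """
    g = np.asarray(g, dtype=float)
    if np.any((g < 0) | (g > 1)):
        raise ValueError("GC content must lie in [0, 1]")
    m_light = MW_GC_SLOPE * g + MW_INTERCEPT
    m_heavy = m_light + MW_MAX_18O_SHIFT
    if m_light.ndim == 0:
        return float(m_light), float(m_heavy)
    return m_light, m_heavy


def eaf_from_wad_shift(w_label, w_light, gc=None):
    """Excess atom fraction 18O from the shift in weighted average density.

    The observed density ratio gives the labeled molecular weight
    ``M_lab = (dW / W_light + 1) * M_light``; EAF is the labeled fraction of
    the maximal 18O weight gain, corrected for natural 18O abundance::

        EAF = (M_lab - M_light) / (M_heavymax - M_light) * (1 - a18O)

    The raw estimate may be negative; truncation to zero is a treatment-level
    reporting rule applied downstream, not here.
    """
    w_label = np.asarray(w_label, dtype=float)
    w_light = np.asarray(w_light, dtype=float)
    if np.any(w_light <= 0):
        raise ValueError("W_light must be positive")
    if gc is None:
        gc = gc_from_density(w_light, warn=False)
    m_light, m_heavy = molecular_weights(gc)
    m_lab = ((w_label - w_light) / w_light + 1.0) * np.asarray(m_light)
    eaf = (m_lab - m_light) / (np.asarray(m_heavy) - m_light) * (1.0 - NATURAL_ABUNDANCE_18O)
    return float(eaf) if eaf.ndim == 0 else eaf


def unlabeled_density(gc):
    """Buoyant density (g mL^-1) of unlabeled DNA with GC content ``gc``."""
    return DENSITY_INTERCEPT + DENSITY_SLOPE * np.asarray(gc, dtype=float)


def labeled_density(gc, eaf):
    """Buoyant density of DNA with GC ``gc`` and 18O excess atom fraction ``eaf``.

    Exact inverse of :func:`eaf_from_wad_shift`: the labeled molecular weight is
    reconstructed from EAF and converted to a density via the light density and
    the weight ratio.  Round-tripping density -> EAF -> density is an identity.
    """
    gc = np.asarray(gc, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    m_light, m_heavy = molecular_weights(gc)
    m_light = np.asarray(m_light, dtype=float)
    m_heavy = np.asarray(m_heavy, dtype=float)
    m_lab = m_light + eaf / (1.0 - NATURAL_ABUNDANCE_18O) * (m_heavy - m_light)
    return unlabeled_density(gc) * m_lab / m_light


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class EafModel:
    """Per-taxon 18O excess atom fraction estimator for a fractionated qSIP experiment.

    Parameters
    ----------
    data : QsipDataset or None
        Bundle of fraction metadata and counts (see :mod:`fieldqsip.data`).
        Alternatively pass ``fractions`` and ``counts`` explicitly.
    fractions : DataFrame
        One row per tube x fraction with columns ``tube_id``, ``treatment``,
        ``block``, ``isotope``, ``fraction_idx``, ``density_g_ml``,
        ``total_16s_copies``.
    counts : DataFrame
        Taxa x fraction-samples; column names ``"<tube_id>.F<fraction_idx>"``.
        May hold read counts or relative abundances — columns are normalised
        to relative abundance internally.
    min_consecutive : int
        A taxon enters the WAD calculation of a tube only if it occurs in at
        least this many consecutive fractions of that tube.
    block_average : {"eaf", "wad"}
        Whether per-block EAFs are averaged ("eaf", default) or per-block WAD
        shifts are averaged before a single conversion to EAF ("wad").
    light_fallback : bool
        If the paired ``16O`` tube of a block fails the filter for a taxon,
        fall back to that taxon's mean unlabeled WAD over passing ``16O``
        tubes of the same treatment (flagged in the results).
    """

    def __init__(
        self,
        data=None,
        *,
        fractions: pd.DataFrame | None = None,
        counts: pd.DataFrame | None = None,
        min_consecutive: int = 3,
        block_average: str = "eaf",
        light_fallback: bool = True,
        light_isotope: str = "16O",
        heavy_isotope: str = "18O",
    ):
        if data is not None:
            fractions = data.fractions
            counts = data.counts
        if fractions is None or counts is None:
            raise ValueError("provide a dataset or both fractions and counts")
        if block_average not in ("eaf", "wad"):
            raise ValueError("block_average must be 'eaf' or 'wad'")
        self.fractions = fractions.copy()
        self.counts = counts.copy()
        self.min_consecutive = int(min_consecutive)
        self.block_average = block_average
        self.light_fallback = bool(light_fallback)
        self.light_isotope = light_isotope
        self.heavy_isotope = heavy_isotope
        self._validate()

    def _validate(self) -> None:
        required = {
            "tube_id", "treatment", "block", "isotope",
            "fraction_idx", "density_g_ml", "total_16s_copies",
        }
        missing = required - set(self.fractions.columns)
        if missing:
            raise ValueError(f"fraction table missing columns: {sorted(missing)}")
        if (self.fractions["total_16s_copies"] < 0).any():
            raise ValueError("negative qPCR totals")
        for tube, sub in self.fractions.groupby("tube_id"):
            d = sub.sort_values("fraction_idx")["density_g_ml"].to_numpy()
            if not np.all(np.diff(d) > 0):
                raise ValueError(f"densities not strictly increasing in tube {tube}")

    # -- per-tube WAD ------------------------------------------------------

    def _tube_wads(self):
        """WAD, filter flag and fraction counts for every taxon in every tube."""
        taxa = self.counts.index
        records = []
        wad = {}
        passed = {}
        for tube, sub in self.fractions.groupby("tube_id", sort=False):
            sub = sub.sort_values("fraction_idx")
            cols = [f"{tube}.F{int(i)}" for i in sub["fraction_idx"]]
            missing = [c for c in cols if c not in self.counts.columns]
            if missing:
                raise ValueError(f"counts matrix missing samples: {missing[:3]}...")
            mat = self.counts[cols].to_numpy(dtype=float)
            colsum = mat.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(colsum > 0, mat / colsum, 0.0)
            y = p * sub["total_16s_copies"].to_numpy()[None, :]
            ok = _runs_ge(y > 0, self.min_consecutive)
            ysum = y.sum(axis=1)
            x = sub["density_g_ml"].to_numpy()
            with np.errstate(invalid="ignore", divide="ignore"):
                w = np.where((ysum > 0) & ok, (x[None, :] * y).sum(axis=1) / ysum, np.nan)
            wad[tube] = pd.Series(w, index=taxa)
            passed[tube] = pd.Series(ok, index=taxa)
            n_used = (y > 0).sum(axis=1)
            meta = sub.iloc[0]
            records.append(pd.DataFrame({
                "taxon_id": taxa,
                "tube_id": tube,
                "treatment": meta["treatment"],
                "block": meta["block"],
                "isotope": meta["isotope"],
                "wad": w,
                "n_fractions_used": n_used,
                "passed_filter": ok,
            }))
        return pd.concat(records, ignore_index=True), wad, passed

    def _pairing(self):
        """(treatment, block) -> (light tube, heavy tube); errors on mismatch."""
        meta = self.fractions[["tube_id", "treatment", "block", "isotope"]].drop_duplicates()
        pairs = {}
        for (tr, bl), sub in meta.groupby(["treatment", "block"]):
            light = sub.loc[sub["isotope"] == self.light_isotope, "tube_id"].tolist()
            heavy = sub.loc[sub["isotope"] == self.heavy_isotope, "tube_id"].tolist()
            if len(light) != 1 or len(heavy) != 1:
                raise ValueError(
                    f"treatment {tr!r} block {bl!r}: expected exactly one "
                    f"{self.light_isotope} and one {self.heavy_isotope} tube, "
                    f"got {len(light)} and {len(heavy)}"
                )
            pairs[(tr, bl)] = (light[0], heavy[0])
        return pairs

    # -- fitting -----------------------------------------------------------

    def fit(self, n_boot: int = 1000, ci_level: float = 0.90, seed=None) -> "EafResults":
        """Estimate per-taxon EAF per treatment with bootstrap confidence intervals.

        Per block, the WAD shift between the paired ``18O`` and ``16O`` tubes is
        converted to a raw EAF; treatment estimates average over qualifying
        blocks, confidence intervals come from resampling blocks with
        replacement, and negative treatment means are truncated to zero
        (flagged).  Taxa with no qualifying block in a treatment are absent
        from that treatment's table.
        """
        if not 0 < ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        rng = np.random.default_rng(seed)
        wad_table, wad, _ = self._tube_wads()
        pairs = self._pairing()
        taxa = self.counts.index

        # mean unlabeled WAD per taxon per treatment (fallback reference)
        light_mean: dict[str, pd.Series] = {}
        for tr in self.fractions["treatment"].unique():
            tubes = [t for (trr, _), (t, _h) in pairs.items() if trr == tr]
            light_mean[tr] = pd.concat([wad[t] for t in tubes], axis=1).mean(axis=1)

        block_rows = []
        for (tr, bl), (light_tube, heavy_tube) in sorted(pairs.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1]))):
            w_heavy = wad[heavy_tube].to_numpy()
            w_light_paired = wad[light_tube].to_numpy()
            w_light_fb = light_mean[tr].to_numpy()
            used_fb = np.isnan(w_light_paired) & ~np.isnan(w_light_fb)
            w_light = np.where(np.isnan(w_light_paired) & self.light_fallback,
                               w_light_fb, w_light_paired)
            ok = ~np.isnan(w_heavy) & ~np.isnan(w_light)
            if not ok.any():
                continue
            eaf_raw = np.full(len(taxa), np.nan)
            eaf_raw[ok] = eaf_from_wad_shift(w_heavy[ok], w_light[ok])
            block_rows.append(pd.DataFrame({
                "taxon_id": taxa,
                "treatment": tr,
                "block": bl,
                "w_light": w_light,
                "w_label": w_heavy,
                "eaf_raw": eaf_raw,
                "light_fallback": used_fb & self.light_fallback & ok,
            })[ok])
        if not block_rows:
            raise ValueError("no taxon qualified in any block")
        block_table = pd.concat(block_rows, ignore_index=True)

        eaf_table = self._aggregate(block_table, n_boot=n_boot, ci_level=ci_level, rng=rng)
        n_excluded = len(taxa) - eaf_table["taxon_id"].nunique()
        logger.info(
            "EAF fit: %d taxa, %d retained in >=1 treatment, %d excluded",
            len(taxa), eaf_table["taxon_id"].nunique(), n_excluded,
        )
        return EafResults(
            model=self,
            eaf_table=eaf_table,
            block_table=block_table,
            wad_table=wad_table,
            n_boot=n_boot,
            ci_level=ci_level,
        )

    def _aggregate(self, block_table, *, n_boot, ci_level, rng):
        alpha = (1.0 - ci_level) / 2.0
        out = []
        for tr, sub in block_table.groupby("treatment", sort=False):
            blocks = sorted(sub["block"].unique())
            b_index = {b: i for i, b in enumerate(blocks)}
            piv = np.full((sub["taxon_id"].nunique(), len(blocks)), np.nan)
            tax_ids = sub["taxon_id"].unique()
            t_index = {t: i for i, t in enumerate(tax_ids)}
            w_light_piv = np.full_like(piv, np.nan)
            fb_any = np.zeros(len(tax_ids), dtype=bool)
            for row in sub.itertuples(index=False):
                i, j = t_index[row.taxon_id], b_index[row.block]
                piv[i, j] = row.eaf_raw
                w_light_piv[i, j] = row.w_light
                fb_any[i] |= bool(row.light_fallback)

            if self.block_average == "eaf":
                raw_mean = np.nanmean(piv, axis=1)
            else:  # average WAD shifts, then convert once
                w_label_piv = np.full_like(piv, np.nan)
                for row in sub.itertuples(index=False):
                    w_label_piv[t_index[row.taxon_id], b_index[row.block]] = row.w_label
                wl = np.nanmean(w_light_piv, axis=1)
                raw_mean = eaf_from_wad_shift(np.nanmean(w_label_piv, axis=1), wl)

            draws = rng.integers(0, len(blocks), size=(n_boot, len(blocks)))
            # boot[i, r] = mean over drawn blocks of taxon i (NaN-aware)
            sampled = piv[:, draws]                      # (taxa, n_boot, n_blocks)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                boot = np.nanmean(sampled, axis=2)
                ci_lo = np.nanpercentile(boot, 100 * alpha, axis=1)
                ci_hi = np.nanpercentile(boot, 100 * (1 - alpha), axis=1)

            n_blocks_used = (~np.isnan(piv)).sum(axis=1)
            w_light_mean = np.nanmean(w_light_piv, axis=1)
            gc = gc_from_density(w_light_mean, warn=False)
            m_light, m_heavy = molecular_weights(gc)
            truncated = raw_mean < 0
            mean_eaf = np.where(truncated, 0.0, raw_mean)
            out.append(pd.DataFrame({
                "taxon_id": tax_ids,
                "treatment": tr,
                "mean_eaf": mean_eaf,
                "raw_mean_eaf": raw_mean,
                "ci_lo": ci_lo,
                "ci_hi": ci_hi,
                "n_blocks": n_blocks_used,
                "truncated": truncated,
                "growing": mean_eaf > 0,
                "light_fallback": fb_any,
                "gc": gc,
                "m_light": m_light,
                "m_heavymax": m_heavy,
            }))
        return pd.concat(out, ignore_index=True)


@dataclass
class EafResults:
    """Fitted per-taxon EAF estimates.

    Attributes
    ----------
    eaf_table : DataFrame
        One row per (taxon, treatment): truncated mean EAF, raw mean,
        bootstrap CI, block count, flags, GC and molecular weights.
    block_table : DataFrame
        Per-block raw EAFs and the WADs they came from.
    wad_table : DataFrame
        Per-tube WAD, fraction counts and filter flags for every taxon.
    """

    model: EafModel
    eaf_table: pd.DataFrame
    block_table: pd.DataFrame
    wad_table: pd.DataFrame
    n_boot: int
    ci_level: float
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def treatments(self) -> list:
        return list(self.eaf_table["treatment"].unique())

    def treatment_table(self, treatment) -> pd.DataFrame:
        sub = self.eaf_table[self.eaf_table["treatment"] == treatment]
        if sub.empty:
            raise KeyError(f"no such treatment: {treatment!r}")
        return sub.set_index("taxon_id")

    def growing_taxa(self, treatment) -> pd.Index:
        sub = self.treatment_table(treatment)
        return sub.index[sub["growing"]]

    def eaf_series(self, treatment, growing_only: bool = True) -> pd.Series:
        """Post-truncation mean EAF per taxon for one treatment."""
        sub = self.treatment_table(treatment)
        if growing_only:
            sub = sub[sub["growing"]]
        return sub["mean_eaf"]

    def summary(self) -> str:
        lines = [
            "18O-qSIP excess atom fraction estimates",
            f"  taxa in input        : {len(self.model.counts.index)}",
            f"  bootstrap resamples  : {self.n_boot}  (CI level {self.ci_level:.0%})",
            "",
            f"  {'treatment':<16}{'n taxa':>8}{'growing':>9}{'mean EAF':>10}{'truncated':>11}",
        ]
        for tr in self.treatments:
            sub = self.treatment_table(tr)
            lines.append(
                f"  {str(tr):<16}{len(sub):>8}{int(sub['growing'].sum()):>9}"
                f"{sub.loc[sub['growing'], 'mean_eaf'].mean():>10.4f}"
                f"{int(sub['truncated'].sum()):>11}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        cols = ["taxon_id", "treatment", "mean_eaf", "ci_lo", "ci_hi",
                "n_blocks", "truncated", "growing"]
        self.eaf_table[cols].to_csv(path, sep="\t", index=False)

    def plot_treatment_boxplot(self, ax=None, growing_only: bool = True):
        """Boxplot of per-taxon EAF by treatment (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        data = [self.eaf_series(tr, growing_only=growing_only).to_numpy()
                for tr in self.treatments]
        ax.boxplot(data, tick_labels=[str(t) for t in self.treatments])
        ax.set_ylabel("excess atom fraction $^{18}$O")
        return ax
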