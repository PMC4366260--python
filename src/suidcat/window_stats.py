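"""Per-window genome features and variance decomposition of variability.

Features per ~1 Mb window: SNP count (and per kb), transition/transversion
counts over biallelic SNPs, GC percentage, CpG dinucleotide count, gene
density (genes overlapping a window boundary are discarded entirely), mean
missing rate, and (log) recombination rate.

Two mirrored linear models relate variability to genome context: SNP density
regressed on Ts/Tv plus context covariates, and Ts/Tv regressed on SNP
density plus the same covariates.  All variables except the missing rate are
standardized; recombination rates are log-transformed because their raw
distribution is strongly right-skewed.  Each covariate's contribution is
summarized as its increase in R^2 when added sequentially, with variables
ordered greedily by marginal gain, so the sequential increments sum exactly
to the full-model R^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .variant_store import GenotypeMatrix

__all__ = [
    "WINDOW_SIZE",
    "compute_window_features",
    "fit_variability_model",
    "RegressionResult",
]

WINDOW_SIZE = 1_000_000

TRANSITIONS = ({"A", "G"}, {"C", "T"})


def _is_transition(ref: str, alt: str) -> bool:
    pair = {ref, alt}
    return pair in TRANSITIONS


def _tile_windows(length: int, window_size: int) -> pd.DataFrame:
    starts = np.arange(0, length, window_size)
    ends = np.minimum(starts + window_size, length)
    return pd.DataFrame({"start": starts, "end": ends})


def compute_window_features(
    matrix: GenotypeMatrix,
    reference_seq: str,
    genes: pd.DataFrame,
    recmap: pd.DataFrame,
    window_size: int = WINDOW_SIZE,
    windows: pd.DataFrame | None = None,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Per-window feature table for a single chromosome.

    Parameters
    ----------
    matrix
        Merged genotype matrix (single contig).
    reference_seq
        Reference sequence of that contig.
    genes
        Frame with ``start``, ``end`` columns (0-based half-open).
    recmap
        Frame with ``window_start``, ``window_end``, ``cm_per_mb``; rates are
        averaged over each window weighted by overlap.
    window_size
        Tile width; ignored when ``windows`` (a ``start``/``end`` frame, e.g.
        read from BED) is given, which allows reproducing any partitioning.
    samples
        Samples entering the missing-rate average (default: all).

    Notes
    -----
    Multiallelic sites count toward ``n_snps`` but not toward Ts/Tv.  Windows
    consisting entirely of N bases are flagged (``all_n``) with undefined
    composition features.  CpG dinucleotides are counted within the window
    slice.
    """
    chroms = matrix.sites["chrom"].unique()
    if len(chroms) > 1:
        raise ValueError("feature computation expects a single chromosome")
    if windows is None:
        windows = _tile_windows(len(reference_seq), window_size)
    if samples is None:
        sample_idx = np.arange(matrix.n_samples)
    else:
        sample_idx = np.array([matrix.sample_index(s) for s in samples])

    pos0 = matrix.sites["pos"].to_numpy() - 1       # back to 0-based
    called = matrix.called_mask()[:, sample_idx]
    n_alts = matrix.sites["alts"].map(len).to_numpy()

    gene_starts = genes["start"].to_numpy() if len(genes) else np.array([], dtype=int)
    gene_ends = genes["end"].to_numpy() if len(genes) else np.array([], dtype=int)

    rows = []
    for _, w in windows.iterrows():
        start, end = int(w["start"]), int(w["end"])
        width = end - start
        in_w = (pos0 >= start) & (pos0 < end)
        idx = np.nonzero(in_w)[0]
        n_snps = int(idx.size)

        ts = tv = 0
        for s in idx:
            if n_alts[s] != 1:
                continue
            row = matrix.sites.iloc[s]
            if _is_transition(row["ref"], row["alts"][0]):
                ts += 1
            else:
                tv += 1

        seq = reference_seq[start:end].upper()
        non_n = width - seq.count("N")
        all_n = non_n == 0
        gc_pct = (
            np.nan if all_n else 100.0 * (seq.count("G") + seq.count("C")) / non_n
        )
        cpg = np.nan if all_n else float(seq.count("CG"))

        # genes fully inside this window; boundary-spanning genes discarded
        inside = (gene_starts >= start) & (gene_ends <= end)
        gene_bp = int((gene_ends[inside] - gene_starts[inside]).sum())
        gene_density = gene_bp / width

        if n_snps:
            missing_rate = float(1.0 - called[idx].mean())
        else:
            missing_rate = np.nan

        ov_start = np.maximum(recmap["window_start"].to_numpy(), start)
        ov_end = np.minimum(recmap["window_end"].to_numpy(), end)
        ov = np.clip(ov_end - ov_start, 0, None).astype(float)
        rec = (
            float(np.average(recmap["cm_per_mb"], weights=ov))
            if ov.sum() > 0 else np.nan
        )

        rows.append({
            "chrom": chroms[0] if len(chroms) else "1",
            "start": start, "end": end,
            "n_snps": n_snps,
            "n_snps_per_kb": 1000.0 * n_snps / width,
            "ts_count": ts, "tv_count": tv,
            "ts_tv": ts / tv if tv > 0 else np.nan,
            "gc_pct": gc_pct,
            "cpg_count": cpg,
            "cpg_per_kb": np.nan if all_n else 1000.0 * cpg / width,
            "gene_density": gene_density,
            "missing_rate": missing_rate,
            "rec_rate": rec,
            "log_rec_rate": np.log(rec) if rec and rec > 0 else np.nan,
            "all_n": all_n,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

RESPONSES = {
    "n_snps": ("n_snps_per_kb",
               ["ts_tv", "log_rec_rate", "gc_pct", "cpg_per_kb",
                "gene_density", "missing_rate"]),
    "ts_tv": ("ts_tv",
              ["n_snps_per_kb", "log_rec_rate", "gc_pct", "cpg_per_kb",
               "gene_density", "missing_rate"]),
}

#: variables entering the model on their raw scale
UNSTANDARDIZED = {"missing_rate"}


@dataclass
class RegressionResult:
    """Sequential variance decomposition of one window-level model."""

    response: str
    table: pd.DataFrame          # variable, estimate, sd, t, incr_r2 (greedy order)
    total_r2: float
    order: list[str]
    n_windows: int
    condition_number: float
    collinearity_warning: bool

    def __str__(self) -> str:  # pragma: no cover - convenience only
        return (
            f"{self.response} ~ {' + '.join(self.order)}; "
            f"R^2 = {self.total_r2:.3f} over {self.n_windows} windows"
        )


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return float(model.rsquared)


def fit_variability_model(
    table: pd.DataFrame,
    response: str = "n_snps",
    predictors: list[str] | None = None,
    order: list[str] | None = None,
) -> RegressionResult:
    """OLS of a window statistic on genome-context covariates.

    Complete-case windows only (windows without transversions have undefined
    Ts/Tv and drop out).  Standardization (z-score) is applied to the
    response and all predictors except those in ``UNSTANDARDIZED``, computed
    on the analyzed window set.  ``order`` fixes the sequential-addition
    order; by default variables are added greedily, largest marginal R^2
    gain first.
    """
    if response not in RESPONSES:
        raise ValueError(f"response must be one of {sorted(RESPONSES)}")
    y_col, default_preds = RESPONSES[response]
    predictors = list(predictors) if predictors is not None else list(default_preds)

    cols = [y_col] + predictors
    data = table[cols].replace([np.inf, -np.inf], np.nan).dropna()
    n = len(data)
    if n < 10:
        raise ValueError(f"need at least 10 complete windows, got {n}")

    def standardize(col: str, v: pd.Series) -> np.ndarray:
        if col in UNSTANDARDIZED:
            return v.to_numpy(dtype=float)
        sd = v.std(ddof=1)
        if sd == 0:
            return np.zeros(n)
        return ((v - v.mean()) / sd).to_numpy(dtype=float)

    y = standardize(y_col, data[y_col])
    X = {p: standardize(p, data[p]) for p in predictors}

    if order is None:
        remaining = list(predictors)
        order = []
        base = 0.0
        while remaining:
            gains = {}
            for p in remaining:
                cand = np.column_stack([X[q] for q in order + [p]])
                gains[p] = _r2(y, cand) - base
            best = max(gains, key=lambda p: gains[p])
            order.append(best)
            base += gains[best]
            remaining.remove(best)
    else:
        if set(order) != set(predictors):
            raise ValueError("order must be a permutation of the predictors")
        order = list(order)

    # sequential increments
    incr, prev = {}, 0.0
    for k in range(1, len(order) + 1):
        r2 = _r2(y, np.column_stack([X[p] for p in order[:k]]))
        incr[order[k - 1]] = r2 - prev
        prev = r2
    total_r2 = prev

    full = sm.OLS(
        y, sm.add_constant(np.column_stack([X[p] for p in order]))
    ).fit()
    cond = float(np.linalg.cond(np.column_stack([X[p] for p in order])))
    rows = [
        {
            "variable": p,
            "estimate": float(full.params[k + 1]),
            "sd": float(full.bse[k + 1]),
            "t": float(full.tvalues[k + 1]),
            "incr_r2": float(incr[p]),
        }
        for k, p in enumerate(order)
    ]
    return RegressionResult(
        response=response,
        table=pd.DataFrame(rows),
        total_r2=float(total_r2),
        order=order,
        n_windows=n,
        condition_number=cond,
        collinearity_warning=cond > 1e8,
    )
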