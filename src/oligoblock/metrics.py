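"""Depletion-efficiency and library-complexity metrics.

Covers CPM normalization, seeded without-replacement subsampling,
fold-reduction of a blocked target, per-biotype read fractions, detection
counts, a pluggable differential-expression test with repeated-subsampling
concordance, and standardized-residual off-target flagging.

Zero handling: a +0.5-count offset precedes every log transform, and
fold_reduction applies the same continuity correction to both sides whenever
a treated mean CPM is zero; corrected results are flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .depletion_sim import CountTable
from .errors import ConfigError, InputError

log = logging.getLogger(__name__)


def cpm(table: CountTable) -> pd.DataFrame:
    """Counts per million: counts * 1e6 / column sum."""
    sums = table.column_sums()
    zero = sums[sums == 0]
    if len(zero):
        raise InputError(f"zero-sum sample column(s): {list(zero.index)}")
    return table.frame * 1e6 / sums


def _log2_cpm_offset(frame: pd.DataFrame) -> pd.DataFrame:
    """log2 CPM with a +0.5 count offset (columns scaled by raw totals)."""
    sums = frame.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise InputError(f"zero-sum sample column(s): {list(zero.index)}")
    return np.log2((frame + 0.5) * 1e6 / sums)


def subsample_counts(table: CountTable, depth: int, seed: int = 0) -> CountTable:
    """Per column, draw ``depth`` reads without replacement (multivariate
    hypergeometric); column totals are exactly ``depth``."""
    if depth < 0:
        raise InputError("depth must be >= 0")
    sums = table.column_sums()
    short = sums[sums < depth]
    if len(short):
        raise InputError(
            f"depth {depth} exceeds the total of sample(s): {list(short.index)}"
        )
    out = {}
    for j, sample in enumerate(table.sample_ids):
        col = table.frame[sample].to_numpy(dtype=np.int64)
        if col.sum() == depth:
            out[sample] = col
        else:
            rng = np.random.default_rng([seed, j])
            out[sample] = rng.multivariate_hypergeometric(col, depth, method="marginals")
    frame = pd.DataFrame(out, index=table.frame.index)
    return CountTable(frame)


@dataclass
class FoldReduction:
    value: float
    control_cpm: float
    treated_cpm: float
    continuity_corrected: bool

    def __float__(self) -> float:
        return self.value


def fold_reduction(control: CountTable, treated: CountTable, gene: str) -> FoldReduction:
    """Mean control CPM / mean treated CPM for one gene.

    CPM is computed per sample and averaged across replicates. If either
    mean is zero, both sides are recomputed with a +0.5-count continuity
    correction and the result is flagged.
    """
    for name, tbl in (("control", control), ("treated", treated)):
        if gene not in tbl.frame.index:
            raise InputError(f"gene {gene!r} absent from the {name} table")
    c = cpm(control).loc[gene].mean()
    t = cpm(treated).loc[gene].mean()
    corrected = False
    if t == 0.0 or c == 0.0:
        corrected = True
        c = (((control.frame.loc[gene] + 0.5) * 1e6) / (control.column_sums() + 0.5)).mean()
        t = (((treated.frame.loc[gene] + 0.5) * 1e6) / (treated.column_sums() + 0.5)).mean()
    return FoldReduction(
        value=float(c / t),
        control_cpm=float(c),
        treated_cpm=float(t),
        continuity_corrected=corrected,
    )


def biotype_fractions(table: CountTable, biotype_map: Dict[str, str]) -> pd.DataFrame:
    """Fraction of each column's reads per biotype; unannotated mass is
    reported as 'other'. Rows: biotypes (+ 'other'); columns: samples."""
    if not any(g in biotype_map for g in table.frame.index):
        raise InputError("biotype map covers none of the table's genes")
    sums = table.column_sums()
    zero = sums[sums == 0]
    if len(zero):
        raise InputError(f"zero-sum sample column(s): {list(zero.index)}")
    biotypes = pd.Series(
        [biotype_map.get(g, "other") for g in table.frame.index],
        index=table.frame.index,
    )
    grouped = table.frame.groupby(biotypes).sum()
    fractions = grouped / sums
    if "other" not in fractions.index:
        fractions.loc["other"] = 0.0
    ordered = sorted(i for i in fractions.index if i != "other") + ["other"]
    return fractions.loc[ordered]


def detected_genes(table: CountTable, min_count: int = 10) -> pd.Series:
    """Number of genes with count >= min_count, per sample."""
    return (table.frame >= min_count).sum(axis=0)


def detect_features(table: CountTable, min_cpm: float = 0.5) -> Dict[str, Set[str]]:
    """Features with CPM strictly greater than ``min_cpm``, per sample."""
    mat = cpm(table)
    return {s: set(mat.index[mat[s] > min_cpm]) for s in mat.columns}


@dataclass
class DEResult:
    """Per-gene differential-expression table.

    ``table`` columns: log2_fold_change, pvalue, padj, filtered. Filtered
    genes (total RPM below the filter) carry no p-value (NaN).
    """

    table: pd.DataFrame
    alpha: float
    engine: str

    @property
    def significant(self) -> Set[str]:
        ok = self.table["padj"] < self.alpha
        return set(self.table.index[ok.fillna(False)])


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaN entries propagate as NaN."""
    p = np.asarray(pvalues, dtype=float)
    adj = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return adj
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    adj[mask] = out
    return adj


def welch_t_engine(log_a: np.ndarray, log_b: np.ndarray) -> np.ndarray:
    """Default engine: two-sample unequal-variance t-test per gene on
    log2-CPM. Genes with zero variance in both groups get p = 1 when the
    means agree and p = 0 otherwise."""
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-identical rows (planted zero-variance genes) are handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(log_a, log_b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    var_a = log_a.var(axis=1, ddof=1)
    var_b = log_b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    same_mean = np.isclose(log_a.mean(axis=1), log_b.mean(axis=1))
    p[degenerate & same_mean] = 1.0
    p[degenerate & ~same_mean] = 0.0
    return p


Engine = Callable[[np.ndarray, np.ndarray], np.ndarray]


def de_test(
    group_a: CountTable,
    group_b: CountTable,
    min_rpm: float = 10.0,
    alpha: float = 0.05,
    engine: Optional[Engine] = None,
) -> DEResult:
    """Filter low-abundance genes, then test each remaining gene.

    The abundance filter keeps genes whose summed reads-per-million over all
    samples (both groups) is >= ``min_rpm``. The engine is pluggable so a
    voom-style fit can be substituted; the default is a Welch t-test on
    log2-CPM with a +0.5-count offset, followed by Benjamini-Hochberg
    adjustment.
    """
    if len(group_a.sample_ids) < 2 or len(group_b.sample_ids) < 2:
        raise InputError("de_test requires at least 2 samples per group")
    if list(group_a.frame.index) != list(group_b.frame.index):
        raise InputError("groups must share an identical gene index")
    engine_fn = engine or welch_t_engine
    engine_name = getattr(engine_fn, "__name__", "custom")

    rpm_a = cpm(group_a)
    rpm_b = cpm(group_b)
    total_rpm = rpm_a.sum(axis=1) + rpm_b.sum(axis=1)
    keep = total_rpm >= min_rpm

    log_a = _log2_cpm_offset(group_a.frame).to_numpy()
    log_b = _log2_cpm_offset(group_b.frame).to_numpy()
    lfc = log_b.mean(axis=1) - log_a.mean(axis=1)

    pvals = np.full(len(keep), np.nan)
    if keep.any():
        idx = keep.to_numpy()
        pvals[idx] = engine_fn(log_a[idx], log_b[idx])
    padj = benjamini_hochberg(pvals)
    table = pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "pvalue": pvals,
            "padj": padj,
            "filtered": ~keep,
        },
        index=group_a.frame.index,
    )
    return DEResult(table=table, alpha=alpha, engine=engine_name)


@dataclass
class ConcordanceResult:
    """Pairwise overlap of significant-gene sets across subsamples."""

    depth: int
    significant_sets: List[Set[str]]
    pair_overlaps: pd.DataFrame  # i, j, intersection, union, jaccard_pct
    concordance_pct: float


def _jaccard_pct(a: Set[str], b: Set[str]) -> float:
    if not a and not b:
        return 100.0  # identical (empty) sets
    return 100.0 * len(a & b) / len(a | b)


def de_concordance(
    group_a: CountTable,
    group_b: CountTable,
    depth: int,
    n_subsamples: int = 4,
    alpha: float = 0.05,
    seed: int = 0,
    min_rpm: float = 10.0,
    engine: Optional[Engine] = None,
) -> ConcordanceResult:
    """Repeatedly subsample both groups to ``depth``, run the DE test on each
    subsample, and report pairwise Jaccard % of the significant sets.

    Raw per-pair overlap counts ship alongside so alternative concordance
    definitions can be computed.
    """
    if n_subsamples < 2:
        raise ConfigError("need at least 2 subsamples")
    sets: List[Set[str]] = []
    for i in range(n_subsamples):
        sub_a = subsample_counts(group_a, depth, seed=seed * 1_000_003 + 2 * i)
        sub_b = subsample_counts(group_b, depth, seed=seed * 1_000_003 + 2 * i + 1)
        res = de_test(sub_a, sub_b, min_rpm=min_rpm, alpha=alpha, engine=engine)
        sets.append(res.significant)
    rows = []
    for i, j in combinations(range(n_subsamples), 2):
        a, b = sets[i], sets[j]
        rows.append(
            {
                "i": i,
                "j": j,
                "intersection": len(a & b),
                "union": len(a | b),
                "jaccard_pct": _jaccard_pct(a, b),
            }
        )
    pair_overlaps = pd.DataFrame(rows)
    return ConcordanceResult(
        depth=depth,
        significant_sets=sets,
        pair_overlaps=pair_overlaps,
        concordance_pct=float(pair_overlaps["jaccard_pct"].mean()),
    )


@dataclass
class OutlierFlag:
    gene: str
    direction: str  # "lower" | "higher" (in treated relative to the fit)
    mean_standardized_residual: float


def flag_offtarget_outliers(
    control: CountTable,
    treated: CountTable,
    threshold_sd: float = 2.0,
    min_count: int = 10,
    exclude: Optional[Sequence[str]] = None,
) -> List[OutlierFlag]:
    """Genes whose treated-vs-control abundance deviates from the per-
    replicate regression line by more than ``threshold_sd`` standardized
    residuals, in the same direction, in every replicate pair.

    Columns are paired positionally (replicate i of control with replicate i
    of treated). Only genes with at least ``min_count`` mean counts in the
    control libraries enter the fit, mirroring a detected-genes analysis;
    low-count noise would otherwise dominate the residual tails. ``exclude``
    removes genes from the analysis entirely — above all the blocked target
    itself, whose huge planned shift would otherwise tilt the fit.
    """
    if len(control.sample_ids) != len(treated.sample_ids):
        raise InputError("control and treated must have matching replicate structure")
    if len(control.sample_ids) < 1:
        raise InputError("need at least one replicate pair")
    if list(control.frame.index) != list(treated.frame.index):
        raise InputError("tables must share an identical gene index")

    keep = control.frame.mean(axis=1) >= min_count
    if exclude:
        keep &= ~control.frame.index.isin(list(exclude))
    if not keep.any():
        raise InputError(f"no genes pass the min_count={min_count} detection filter")
    log_c = _log2_cpm_offset(control.frame.loc[keep]).to_numpy()
    log_t = _log2_cpm_offset(treated.frame.loc[keep]).to_numpy()
    genes = control.frame.index[keep]

    n_pairs = log_c.shape[1]
    z_all = np.empty((log_c.shape[0], n_pairs))
    for p in range(n_pairs):
        x, y = log_c[:, p], log_t[:, p]
        slope, intercept = np.polyfit(x, y, deg=1)
        resid = y - (slope * x + intercept)
        sd = resid.std(ddof=2) if resid.size > 2 else resid.std(ddof=0)
        if sd == 0:
            z_all[:, p] = 0.0
        else:
            z_all[:, p] = resid / sd

    # consistent direction required: all pairs above +threshold or all below
    flagged = (z_all > threshold_sd).all(axis=1) | (z_all < -threshold_sd).all(axis=1)
    flags = []
    for gi in np.flatnonzero(flagged):
        mean_z = float(z_all[gi].mean())
        flags.append(
            OutlierFlag(
                gene=str(genes[gi]),
                direction="lower" if mean_z < 0 else "higher",
                mean_standardized_residual=mean_z,
            )
        )
    flags.sort(key=lambda f: f.gene)
    return flags
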