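"""Simulation of the sequencing benefit of blocking an abundant transcript.

Given a background gene-abundance distribution (derived from a real or
synthetic count table with the dominant target removed), the simulator draws
libraries over a grid of sequencing depth, initial target fraction ``f0``
and depletion efficiency ``d``, and counts detected genes per draw.

Reallocation convention: depleted target reads are replaced by background
reads at fixed total depth. After removing a fraction ``d`` of the target's
molecules, its share of the library is

    f_eff = f0 * (1 - d) / (f0 * (1 - d) + (1 - f0))

and every background gene g receives (1 - f_eff) * bg_fraction(g). Sampling
is multinomial (with replacement from the fraction vector) rather than
hypergeometric from one fixed table, because the grid varies ``f0``
continuously; a hypergeometric variant is left as a config stub.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

log = logging.getLogger(__name__)

TARGET_COLUMN = "__target__"


@dataclass
class CountTable:
    """Genes x samples matrix of non-negative integer counts."""

    frame: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate gene ids: {dupes}")
        if not np.issubdtype(self.frame.to_numpy().dtype, np.integer):
            values = self.frame.to_numpy()
            if not np.allclose(values, np.round(values)):
                raise InputError("count table must contain integers")
            self.frame = self.frame.round().astype(np.int64)
        if (self.frame.to_numpy() < 0).any():
            raise InputError("count table contains negative entries")

    @property
    def gene_ids(self) -> List[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.frame.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.frame.to_numpy()

    def column_sums(self) -> pd.Series:
        return self.frame.sum(axis=0)

    @classmethod
    def from_arrays(
        cls, gene_ids: Sequence[str], sample_ids: Sequence[str], counts: np.ndarray
    ) -> "CountTable":
        return cls(
            pd.DataFrame(
                np.asarray(counts, dtype=np.int64),
                index=list(gene_ids),
                columns=list(sample_ids),
            )
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        """First column gene id, remaining columns integer counts; header
        row required."""
        path = Path(path)
        if not path.exists():
            raise InputError(f"count table not found: {path}")
        frame = pd.read_csv(path, sep="\t", index_col=0)
        if frame.shape[1] == 0:
            raise InputError(f"{path}: no sample columns found")
        frame.index = frame.index.astype(str)
        frame.index.name = None
        return cls(frame)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class BackgroundDistribution:
    """Per-gene read fractions after removing the target gene."""

    gene_ids: List[str]
    fractions: np.ndarray
    target_gene: str
    source_sample: Optional[str] = None

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.gene_ids) != self.fractions.size:
            raise InputError("gene_ids and fractions length mismatch")
        if (self.fractions < 0).any():
            raise InputError("background fractions must be non-negative")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise InputError("background fractions must sum to 1")
        if self.target_gene in self.gene_ids:
            raise InputError("target gene must be absent from the background")


def background_distribution(
    table: CountTable, sample: str, target_gene: str
) -> BackgroundDistribution:
    """Fraction of reads per gene after removing the target's reads."""
    if sample not in table.frame.columns:
        raise InputError(f"unknown sample: {sample!r}")
    if target_gene not in table.frame.index:
        raise InputError(f"target gene {target_gene!r} not present in the table")
    col = table.frame[sample]
    background = col.drop(index=target_gene)
    total = int(background.sum())
    if total <= 0:
        raise InputError(
            f"sample {sample!r}: background is all zero after removing {target_gene!r}"
        )
    return BackgroundDistribution(
        gene_ids=list(background.index),
        fractions=background.to_numpy(dtype=float) / total,
        target_gene=target_gene,
        source_sample=sample,
    )


def effective_target_fraction(f0: float, d: float) -> float:
    """Target library share after depleting a fraction ``d`` of its
    molecules and renormalizing at fixed total depth:
    f0 (1 - d) / (f0 (1 - d) + (1 - f0))."""
    if not (0.0 <= f0 < 1.0):
        raise InputError(f"initial fraction f0={f0} outside [0, 1)")
    if not (0.0 <= d <= 1.0):
        raise InputError(f"depletion efficiency d={d} outside [0, 1]")
    remaining = f0 * (1.0 - d)
    return remaining / (remaining + (1.0 - f0))


@dataclass
class DepletionSimConfig:
    depths: Sequence[int] = (500_000, 1_000_000, 2_000_000, 4_000_000, 8_000_000)
    initial_fractions: Sequence[float] = tuple(np.round(np.arange(0.0, 0.91, 0.1), 10))
    efficiencies: Sequence[float] = tuple(np.round(np.arange(0.0, 1.0001, 0.02), 10))
    detection_threshold: int = 10
    n_reps: int = 10
    seed: int = 0
    sampling: str = "multinomial"  # hypergeometric variant: not implemented

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.depths):
            raise ConfigError("depths must be positive")
        if any(not (0.0 <= f < 1.0) for f in self.initial_fractions):
            raise ConfigError("initial fractions must lie in [0, 1)")
        if any(not (0.0 <= d <= 1.0) for d in self.efficiencies):
            raise ConfigError("efficiencies must lie in [0, 1]")
        if self.detection_threshold < 1:
            raise ConfigError("detection threshold must be >= 1")
        if self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")
        if self.sampling != "multinomial":
            raise ConfigError(
                "only multinomial sampling is implemented; the hypergeometric "
                "variant is a documented stub"
            )


@dataclass
class DepletionSimResult:
    grid: pd.DataFrame  # depth, f0, efficiency, rep, detected_genes, target_counts
    n_background_genes: int
    config: DepletionSimConfig

    def summary(self) -> pd.DataFrame:
        """Mean/sd of detected genes and target counts over replicates."""
        g = self.grid.groupby(["depth", "f0", "efficiency"], as_index=False).agg(
            detected_genes_mean=("detected_genes", "mean"),
            detected_genes_sd=("detected_genes", "std"),
            target_counts_mean=("target_counts", "mean"),
            target_counts_sd=("target_counts", "std"),
            n_reps=("rep", "count"),
        )
        return g.fillna({"detected_genes_sd": 0.0, "target_counts_sd": 0.0})


def _cell_rng(seed: int, depth_idx: int, f0_idx: int, rep: int) -> np.random.Generator:
    return np.random.default_rng([seed, depth_idx, f0_idx, rep])


def simulate_depletion(
    bg: BackgroundDistribution, config: DepletionSimConfig
) -> DepletionSimResult:
    """Draw the full (depth x f0 x efficiency x rep) grid.

    Each draw is one multinomial library of exactly ``depth`` reads from the
    merged {target, background} fraction vector; a gene (target included)
    counts as detected when its count >= ``detection_threshold``.
    """
    bg_fractions = bg.fractions
    rows: List[Dict] = []
    threshold = config.detection_threshold
    for (di, depth), (fi, f0) in itertools.product(
        enumerate(config.depths), enumerate(config.initial_fractions)
    ):
        depth = int(depth)
        for rep in range(config.n_reps):
            for d in config.efficiencies:
                # fresh generator per cell, keyed without the efficiency: equal
                # fraction vectors (e.g. any d at f0 = 0) give bit-identical draws
                rng = _cell_rng(config.seed, di, fi, rep)
                f_eff = effective_target_fraction(f0, d)
                p = np.concatenate([[f_eff], (1.0 - f_eff) * bg_fractions])
                draw = rng.multinomial(depth, p / p.sum())
                target_counts = int(draw[0])
                detected = int((draw >= threshold).sum())
                rows.append(
                    {
                        "depth": depth,
                        "f0": f0,
                        "efficiency": d,
                        "rep": rep,
                        "detected_genes": detected,
                        "target_counts": target_counts,
                    }
                )
    grid = pd.DataFrame(rows)
    return DepletionSimResult(
        grid=grid, n_background_genes=len(bg.gene_ids), config=config
    )


def detected_gene_surface(
    result: DepletionSimResult,
    tsv_path: Optional[str | Path] = None,
    plot_path: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Tidy mean-detected-genes surface over (depth, f0, efficiency), with a
    per-(depth, f0) monotonicity summary; optionally written as TSV/plot."""
    if result.grid.empty:
        raise InputError("empty simulation result")
    surface = result.summary()
    gains = (
        surface.sort_values("efficiency")
        .groupby(["depth", "f0"])["detected_genes_mean"]
        .agg(["first", "last"])
    )
    surface = surface.merge(
        (gains["last"] - gains["first"]).rename("total_gain").reset_index(),
        on=["depth", "f0"],
    )
    if tsv_path is not None:
        tsv_path = Path(tsv_path)
        tsv_path.parent.mkdir(parents=True, exist_ok=True)
        surface.to_csv(tsv_path, sep="\t", index=False)
    if plot_path is not None:
        _plot_surface(surface, Path(plot_path))
    return surface


def _plot_surface(surface: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    depths = sorted(surface["depth"].unique())
    fig, axes = plt.subplots(
        1, len(depths), figsize=(3.2 * len(depths), 3.2), sharey=True, squeeze=False
    )
    for ax, depth in zip(axes[0], depths):
        sub = surface[surface["depth"] == depth]
        for f0, grp in sub.groupby("f0"):
            grp = grp.sort_values("efficiency")
            ax.plot(grp["efficiency"], grp["detected_genes_mean"], label=f"f0={f0:g}")
        ax.set_title(f"depth={depth:,}")
        ax.set_xlabel("depletion efficiency")
    axes[0][0].set_ylabel("detected genes (count >= threshold)")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
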