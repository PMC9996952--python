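"""Seeded generators for every input class the toolkit consumes.

Each generator is a pure function of (parameters, seed) — identical outputs
across runs — and returns a :class:`TruthManifest` recording the planted
structure so analysis operations can be validated by round-trip.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .depletion_sim import CountTable, effective_target_fraction
from .errors import ConfigError, InputError
from .sequence_model import TranscriptRecord, Transcriptome
from .target_finder import find_internal_polya

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class TruthManifest:
    kind: str
    seed: int
    params: Dict
    truth: Dict

    def to_json(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=_jsonable)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _scrub_spontaneous_a_runs(
    seq: np.ndarray, tid: str, min_run: int, min_a_fraction: float
) -> np.ndarray:
    """Deterministically rewrite accidental adenosine-rich windows in a
    random background so that the only qualifying sites are planted ones."""
    for _ in range(100):
        record = TranscriptRecord(id=tid, seq=seq.tobytes().decode())
        sites = find_internal_polya(
            record, min_run=min_run, min_a_fraction=min_a_fraction, tail_exclusion=0
        )
        if not sites:
            return seq
        for site in sites:
            span = np.arange(site.interval.start, site.interval.end)
            a_pos = span[seq[span] == ord("A")]
            seq[a_pos[::2]] = ord("C")  # break the run, keep it deterministic
    raise RuntimeError("background scrub did not converge")  # pragma: no cover


def synth_transcriptome(
    n_transcripts: int = 20,
    length_range: Tuple[int, int] = (500, 2000),
    n_polya_sites: int = 2,
    polya_run_length: int = 12,
    n_decoys: int = 3,
    decoy_mismatches: Sequence[int] = (0, 2, 4),
    seed: int = 0,
    k: int = 16,
    window_width: int = 50,
    tail_exclusion: int = 30,
    min_run: int = 8,
    min_a_fraction: float = 0.8,
    guard: int = 10,
) -> Tuple[Transcriptome, TruthManifest]:
    """Random transcripts with planted internal poly(A) sites and decoy
    near-matches of a designated design-window k-mer.

    Transcript ``tx_0001`` carries the planted sites (each a pure A-run
    flanked by non-A guard bases so the planted interval is exactly what the
    site finder must recover). Decoy transcripts ``decoy_N`` each carry one
    copy of the source k-mer with exactly the requested number of
    substitutions. Backgrounds are scrubbed of spontaneous A-rich windows so
    the truth manifest is unambiguous.
    """
    if any(m < 0 for m in decoy_mismatches):
        raise InputError("decoy mismatch counts must be >= 0")
    if n_decoys and len(decoy_mismatches) == 0:
        raise InputError("decoy_mismatches must be non-empty when n_decoys > 0")
    if n_transcripts < 1 + n_decoys:
        raise ConfigError("need at least 1 + n_decoys transcripts")
    lo, hi = length_range
    # geometry: per planted site we need guard + window + guard + run
    site_pitch = window_width + polya_run_length + 2 * guard + 10
    needed = site_pitch * n_polya_sites + tail_exclusion + guard
    if lo < k or hi < needed:
        raise InputError(
            f"infeasible geometry: transcript length range {length_range} cannot "
            f"hold {n_polya_sites} site(s) plus design window(s) (need >= {needed})"
        )
    rng = np.random.default_rng(seed)

    records: List[TranscriptRecord] = []
    truth_sites: List[Dict] = []
    truth_decoys: List[Dict] = []

    # --- target transcript with planted sites
    target_id = "tx_0001"
    tlen = int(rng.integers(max(lo, needed), hi + 1))
    seq = _random_seq(rng, tlen)
    seq = _scrub_spontaneous_a_runs(seq, target_id, min_run, min_a_fraction)
    site_starts = []
    for s in range(n_polya_sites):
        run_start = guard + window_width + guard + s * site_pitch
        run_end = run_start + polya_run_length
        seq[run_start - guard : run_start] = ord("C")
        seq[run_start:run_end] = ord("A")
        seq[run_end : run_end + guard] = ord("C")
        site_starts.append(run_start)
        truth_sites.append(
            {"transcript_id": target_id, "start": run_start, "end": run_end}
        )
    records.append(TranscriptRecord(id=target_id, seq=seq.tobytes().decode()))

    # decoy source: the sense k-mer just 5' of the first planted run's guard,
    # i.e. inside that site's design window but in scrubbed background
    src_end = site_starts[0] - guard
    src_start = src_end - k
    source_kmer = seq[src_start:src_end].tobytes().decode()

    # --- decoy transcripts
    mism_cycle = list(decoy_mismatches)
    for di in range(n_decoys):
        did = f"decoy_{di + 1}"
        dlen = int(rng.integers(lo, hi + 1))
        dseq = _random_seq(rng, dlen)
        dseq = _scrub_spontaneous_a_runs(dseq, did, min_run, min_a_fraction)
        m = mism_cycle[di % len(mism_cycle)]
        pos = int(rng.integers(guard, dlen - k - guard))
        planted = np.frombuffer(source_kmer.encode(), dtype=np.uint8).copy()
        if m > 0:
            mut_pos = rng.choice(k, size=m, replace=False)
            for p in mut_pos:
                alternatives = BASES[BASES != planted[p]]
                planted[p] = rng.choice(alternatives)
        dseq[pos : pos + k] = planted
        records.append(TranscriptRecord(id=did, seq=dseq.tobytes().decode()))
        truth_decoys.append(
            {
                "transcript_id": did,
                "start": pos,
                "end": pos + k,
                "mismatches": m,
                "seq": planted.tobytes().decode(),
            }
        )

    # --- plain background transcripts
    for bi in range(n_transcripts - 1 - n_decoys):
        bid = f"tx_{bi + 2:04d}"
        blen = int(rng.integers(lo, hi + 1))
        bseq = _scrub_spontaneous_a_runs(_random_seq(rng, blen), bid, min_run, min_a_fraction)
        records.append(TranscriptRecord(id=bid, seq=bseq.tobytes().decode()))

    tx = Transcriptome(records)
    manifest = TruthManifest(
        kind="transcriptome",
        seed=seed,
        params={
            "n_transcripts": n_transcripts,
            "length_range": list(length_range),
            "n_polya_sites": n_polya_sites,
            "polya_run_length": polya_run_length,
            "n_decoys": n_decoys,
            "decoy_mismatches": list(decoy_mismatches),
            "k": k,
            "window_width": window_width,
            "tail_exclusion": tail_exclusion,
            "min_run": min_run,
            "min_a_fraction": min_a_fraction,
            "guard": guard,
        },
        truth={
            "target_transcript": target_id,
            "polya_sites": truth_sites,
            "decoy_source": {
                "transcript_id": target_id,
                "start": src_start,
                "end": src_end,
                "kmer": source_kmer,
            },
            "decoys": truth_decoys,
        },
    )
    return tx, manifest


def _base_fractions(
    rng: np.random.Generator,
    n_genes: int,
    dominant_gene_fraction: float,
    lognormal_sigma: float,
) -> np.ndarray:
    """Long-tailed background with gene 0 optionally forced to a fixed share."""
    weights = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=n_genes)
    fractions = weights / weights.sum()
    if dominant_gene_fraction > 0:
        rest = fractions[1:] / fractions[1:].sum()
        fractions = np.concatenate(
            [[dominant_gene_fraction], (1.0 - dominant_gene_fraction) * rest]
        )
    return fractions


def synth_count_table(
    n_genes: int = 1000,
    depth: int = 1_000_000,
    dominant_gene_fraction: float = 0.0,
    lognormal_sigma: float = 1.5,
    n_samples: int = 1,
    seed: int = 0,
    target_gene: str = "TARGET",
) -> Tuple[CountTable, TruthManifest]:
    """Multinomial libraries over a log-normal background, with one
    designated gene optionally consuming a fixed fraction of reads."""
    if not (0.0 <= dominant_gene_fraction < 1.0):
        raise InputError("dominant_gene_fraction must lie in [0, 1)")
    if n_genes < 2:
        raise ConfigError("need at least 2 genes")
    rng = np.random.default_rng(seed)
    fractions = _base_fractions(rng, n_genes, dominant_gene_fraction, lognormal_sigma)
    gene_ids = [target_gene] + [f"G{i:05d}" for i in range(1, n_genes)]
    counts = np.column_stack(
        [
            np.random.default_rng([seed, 1000 + s]).multinomial(int(depth), fractions)
            for s in range(n_samples)
        ]
    )
    table = CountTable.from_arrays(
        gene_ids, [f"S{s + 1}" for s in range(n_samples)], counts
    )
    manifest = TruthManifest(
        kind="count_table",
        seed=seed,
        params={
            "n_genes": n_genes,
            "depth": int(depth),
            "dominant_gene_fraction": dominant_gene_fraction,
            "lognormal_sigma": lognormal_sigma,
            "n_samples": n_samples,
        },
        truth={
            "target_gene": target_gene,
            "target_fraction": float(fractions[0]),
            "fractions": fractions,
        },
    )
    return table, manifest


def synth_depletion_pair(
    n_genes: int = 1000,
    depth: int = 1_000_000,
    initial_fraction: float = 0.2,
    lognormal_sigma: float = 1.5,
    target_gene: str = "TARGET",
    efficiency: float = 0.9,
    n_replicates: int = 3,
    seed: int = 0,
    offtarget_gene_rank: Optional[int] = None,
    offtarget_suppression: float = 1.0,
    replicate_sigma: float = 0.0,
) -> Tuple[CountTable, CountTable, TruthManifest]:
    """Paired control/treated libraries with the target depleted at a known
    efficiency, optionally with one planted off-target suppressed by a
    stated factor in the treated libraries.

    ``offtarget_gene_rank`` picks the planted off-target as the N-th most
    abundant background gene (rank 0 = most abundant), keeping it well above
    detection thresholds so the round-trip is unambiguous.

    ``replicate_sigma`` adds independent per-replicate lognormal jitter to
    the gene fractions (biological/technical overdispersion on top of the
    multinomial sampling); 0 gives pure multinomial replicates.
    """
    if not (0.0 <= efficiency <= 1.0):
        raise InputError("efficiency must lie in [0, 1]")
    if offtarget_suppression < 1.0:
        raise InputError("offtarget_suppression is a fold-suppression factor >= 1")
    rng = np.random.default_rng(seed)
    fractions = _base_fractions(rng, n_genes, initial_fraction, lognormal_sigma)
    gene_ids = [target_gene] + [f"G{i:05d}" for i in range(1, n_genes)]

    f_eff = effective_target_fraction(initial_fraction, efficiency)
    treated_fracs = fractions.copy()
    treated_fracs[0] = f_eff
    if initial_fraction > 0:
        treated_fracs[1:] = fractions[1:] * (1.0 - f_eff) / (1.0 - initial_fraction)

    offtarget_gene = None
    if offtarget_gene_rank is not None:
        bg_order = np.argsort(fractions[1:])[::-1]
        ot_idx = 1 + int(bg_order[offtarget_gene_rank])
        offtarget_gene = gene_ids[ot_idx]
        treated_fracs[ot_idx] /= offtarget_suppression
    treated_fracs = treated_fracs / treated_fracs.sum()

    def _draw(base: np.ndarray, stream: int) -> np.ndarray:
        rep_rng = np.random.default_rng([seed, stream])
        p = base
        if replicate_sigma > 0:
            p = base * rep_rng.lognormal(0.0, replicate_sigma, size=base.size)
            p = p / p.sum()
        return rep_rng.multinomial(int(depth), p)

    control = np.column_stack([_draw(fractions, 2000 + r) for r in range(n_replicates)])
    treated = np.column_stack([_draw(treated_fracs, 3000 + r) for r in range(n_replicates)])
    samples_c = [f"ctrl_{r + 1}" for r in range(n_replicates)]
    samples_t = [f"trt_{r + 1}" for r in range(n_replicates)]
    control_t = CountTable.from_arrays(gene_ids, samples_c, control)
    treated_t = CountTable.from_arrays(gene_ids, samples_t, treated)
    implied_fold = (
        float(fractions[0] / treated_fracs[0]) if treated_fracs[0] > 0 else float("inf")
    )
    manifest = TruthManifest(
        kind="depletion_pair",
        seed=seed,
        params={
            "n_genes": n_genes,
            "depth": int(depth),
            "initial_fraction": initial_fraction,
            "lognormal_sigma": lognormal_sigma,
            "efficiency": efficiency,
            "n_replicates": n_replicates,
            "offtarget_gene_rank": offtarget_gene_rank,
            "offtarget_suppression": offtarget_suppression,
            "replicate_sigma": replicate_sigma,
        },
        truth={
            "target_gene": target_gene,
            "effective_target_fraction": float(f_eff),
            "implied_fold_reduction": implied_fold,
            "offtarget_gene": offtarget_gene,
        },
    )
    return control_t, treated_t, manifest


def synth_two_group_counts(
    n_genes: int = 2000,
    n_per_group: int = 4,
    frac_de: float = 0.1,
    log2fc: float = 2.0,
    depth: int = 2_000_000,
    lognormal_sigma: float = 1.5,
    seed: int = 0,
) -> Tuple[CountTable, CountTable, TruthManifest]:
    """Two-group libraries with planted symmetric +/- log2fc fold changes on
    a random ``frac_de`` subset of genes."""
    if not (0.0 <= frac_de <= 1.0):
        raise InputError("frac_de must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    base = _base_fractions(rng, n_genes, 0.0, lognormal_sigma)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]

    n_de = int(round(frac_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    signs = np.ones(n_de)
    signs[1::2] = -1.0  # alternate up/down for symmetry
    b_fracs = base.copy()
    realized_lfc = signs * log2fc
    if n_de:
        shifted = base[de_idx] * 2.0 ** (signs * log2fc)
        # rescale the DE set to its original total mass so that every null
        # gene's fraction is exactly unchanged between the groups (no
        # composition bias for the default total-count CPM normalization)
        balance = base[de_idx].sum() / shifted.sum()
        b_fracs[de_idx] = shifted * balance
        realized_lfc = signs * log2fc + np.log2(balance)

    counts_a = np.column_stack(
        [
            np.random.default_rng([seed, 4000 + r]).multinomial(int(depth), base)
            for r in range(n_per_group)
        ]
    )
    counts_b = np.column_stack(
        [
            np.random.default_rng([seed, 5000 + r]).multinomial(int(depth), b_fracs)
            for r in range(n_per_group)
        ]
    )
    group_a = CountTable.from_arrays(
        gene_ids, [f"A{r + 1}" for r in range(n_per_group)], counts_a
    )
    group_b = CountTable.from_arrays(
        gene_ids, [f"B{r + 1}" for r in range(n_per_group)], counts_b
    )
    de_genes = [
        {"gene": gene_ids[g], "log2fc": float(s * log2fc), "realized_log2fc": float(r)}
        for g, s, r in zip(de_idx, signs, np.atleast_1d(realized_lfc))
    ]
    manifest = TruthManifest(
        kind="two_group_counts",
        seed=seed,
        params={
            "n_genes": n_genes,
            "n_per_group": n_per_group,
            "frac_de": frac_de,
            "log2fc": log2fc,
            "depth": int(depth),
            "lognormal_sigma": lognormal_sigma,
        },
        truth={"de_genes": de_genes, "n_de": n_de},
    )
    return group_a, group_b, manifest
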