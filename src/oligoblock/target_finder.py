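"""Locate internal adenosine-rich RT-priming sites and derive design windows.

An internal poly(A) site is an adenosine-rich stretch inside the transcript
body that an oligo(dT) primer can anneal to, producing artifactual 3'-end
reads. "Adenosine-rich" is formalized as: any window of length >= ``min_run``
whose A-fraction is >= ``min_a_fraction``, lying wholly outside the terminal
``tail_exclusion`` nucleotides (so genuine 3' poly(A) tails never qualify).
Overlapping qualifying windows are merged and the merged region is trimmed
to its outermost adenosines, yielding maximal, non-overlapping sites.

The design window in which blocking candidates are tiled sits immediately
5' of the priming site on the sense strand: reverse transcriptase extends
from the oligo(dT) primer towards the transcript 5' end, so an oligo bound
there is hit by the polymerase right after priming.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np

from .errors import ConfigError, InputError
from .sequence_model import Interval, TranscriptRecord

FRAGMENT_ID = "fragment"


@dataclass(frozen=True)
class PolyASite:
    """An internal adenosine-rich priming site on the sense transcript."""

    interval: Interval
    a_fraction: float
    run_length: int

    def __post_init__(self) -> None:
        if self.run_length != self.interval.length:
            raise InputError("PolyASite: run_length must equal interval length")
        if not (0.0 <= self.a_fraction <= 1.0):
            raise InputError("PolyASite: a_fraction outside [0, 1]")


@dataclass(frozen=True)
class DesignWindow:
    """Sense-strand region in which candidate blockers are tiled."""

    interval: Interval
    seq: str
    source_site: Optional[PolyASite] = None
    anchor: Optional[str] = None  # fragment mode: "three_prime_end"
    mode: str = "polya"  # "polya" | "fragment"

    def __post_init__(self) -> None:
        if len(self.seq) != self.interval.length:
            raise InputError("DesignWindow: seq length must equal interval length")
        if self.source_site is not None and self.interval.overlaps(self.source_site.interval):
            raise InputError("DesignWindow must not overlap its source poly(A) site")

    def __len__(self) -> int:
        return self.interval.length


def find_internal_polya(
    transcript: TranscriptRecord,
    min_run: int = 8,
    min_a_fraction: float = 0.8,
    tail_exclusion: int = 30,
) -> List[PolyASite]:
    """Maximal internal adenosine-rich sites, sorted by start.

    Every window of length >= ``min_run`` with A-fraction >= ``min_a_fraction``
    ending at or before ``len(transcript) - tail_exclusion`` contributes its
    positions; connected runs of contributed positions are merged and trimmed
    to the outermost A, giving non-overlapping maximal sites.
    """
    if min_run < 4:
        raise ConfigError(f"min_run={min_run} is degenerate; need min_run >= 4")
    if not (0.0 < min_a_fraction <= 1.0):
        raise ConfigError("min_a_fraction must be in (0, 1]")
    if tail_exclusion < 0:
        raise ConfigError("tail_exclusion must be >= 0")

    seq = transcript.seq
    limit = len(seq) - tail_exclusion  # windows must end at or before limit
    if limit < min_run:
        return []

    is_a = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("A")
    prefix = np.concatenate([[0], np.cumsum(is_a)])  # prefix[i] = #A in seq[:i]

    covered = np.zeros(len(seq), dtype=bool)
    for s in range(0, limit - min_run + 1):
        ends = np.arange(s + min_run, limit + 1)
        if ends.size == 0:
            continue
        frac = (prefix[ends] - prefix[s]) / (ends - s)
        qualifying = ends[frac >= min_a_fraction]
        if qualifying.size:
            covered[s : qualifying.max()] = True

    sites: List[PolyASite] = []
    idx = np.flatnonzero(covered)
    if idx.size == 0:
        return sites
    # connected components of the coverage mask
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    for cs, ce in zip(starts, ends):
        a_pos = np.flatnonzero(is_a[cs:ce])
        if a_pos.size == 0:
            continue
        ts, te = cs + a_pos[0], cs + a_pos[-1] + 1  # trim to outermost A
        interval = Interval(transcript.id, int(ts), int(te))
        a_frac = float((prefix[te] - prefix[ts]) / (te - ts))
        sites.append(PolyASite(interval=interval, a_fraction=a_frac, run_length=te - ts))
    return sites


def design_window(
    site: PolyASite,
    transcript: TranscriptRecord,
    width: int = 50,
) -> DesignWindow:
    """The ``width`` sense-strand bases immediately 5' of the priming site.

    Interval is [max(0, site.start - width), site.start); truncated at the
    transcript 5' end. A site starting at position 0 has no design space.
    """
    if site.interval.transcript_id != transcript.id:
        raise InputError(
            f"site is on {site.interval.transcript_id!r}, not {transcript.id!r}"
        )
    if site.interval.end > len(transcript):
        raise InputError("site extends past the transcript end")
    if site.interval.start == 0:
        raise InputError(
            f"no design space 5' of priming site at {transcript.id}:0"
        )
    if width < 1:
        raise ConfigError("design window width must be >= 1")
    start = max(0, site.interval.start - width)
    end = site.interval.start
    interval = Interval(transcript.id, start, end)
    return DesignWindow(
        interval=interval,
        seq=transcript.seq[start:end],
        source_site=site,
        mode="polya",
    )


def fragment_window(
    fragment_seq: str,
    anchor: str = "three_prime_end",
    k: int = 16,
    transcript_id: str = FRAGMENT_ID,
) -> DesignWindow:
    """Short-RNA mode: the whole fragment is the design window.

    ``anchor`` marks which fragment end the selector should prefer on
    melting-temperature ties; it is recorded verbatim in the output.
    """
    if anchor != "three_prime_end":
        raise InputError(f"unsupported anchor: {anchor!r}")
    from .sequence_model import normalize_sequence

    seq = normalize_sequence(fragment_seq, context="fragment")
    if len(seq) < k:
        raise InputError(
            f"fragment of length {len(seq)} is shorter than oligo length k={k}"
        )
    interval = Interval(transcript_id, 0, len(seq))
    return DesignWindow(interval=interval, seq=seq, anchor=anchor, mode="fragment")


def sites_to_tsv(sites: List[PolyASite], path: str | Path) -> None:
    """Export sites as BED-like TSV (0-based half-open) with 1-based twins."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(
            "transcript_id\tstart\tend\tname\ta_fraction\t"
            "start_1based\tend_1based\n"
        )
        for i, site in enumerate(sites):
            iv = site.interval
            s1, e1 = iv.one_based()
            fh.write(
                f"{iv.transcript_id}\t{iv.start}\t{iv.end}\tpolyA_site_{i + 1}\t"
                f"{site.a_fraction:.4f}\t{s1}\t{e1}\n"
            )
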