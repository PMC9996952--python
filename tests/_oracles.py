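"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's optimized code paths: plain Python
loops and explicit enumeration, so they can serve as oracles.
"""

from typing import List, Tuple


def oracle_hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    n = 0
    for i in range(len(a)):
        if a[i] != b[i]:
            n += 1
    return n


def oracle_polya_sites(
    seq: str, min_run: int, min_a_fraction: float, tail_exclusion: int
) -> List[Tuple[int, int]]:
    """Enumerate every (start, length >= min_run) window; union the
    qualifying ones; trim each connected component to its outermost A."""
    limit = len(seq) - tail_exclusion
    covered = [False] * len(seq)
    for s in range(0, max(0, limit - min_run + 1)):
        for e in range(s + min_run, limit + 1):
            n_a = seq[s:e].count("A")
            if n_a / (e - s) >= min_a_fraction:
                for i in range(s, e):
                    covered[i] = True
    # connected components
    sites = []
    i = 0
    while i < len(seq):
        if not covered[i]:
            i += 1
            continue
        j = i
        while j < len(seq) and covered[j]:
            j += 1
        # trim to outermost A
        ts, te = i, j
        while ts < te and seq[ts] != "A":
            ts += 1
        while te > ts and seq[te - 1] != "A":
            te -= 1
        if ts < te:
            sites.append((ts, te))
        i = j
    return sites


def oracle_offtargets(
    sense_kmer: str,
    transcripts: List[Tuple[str, str]],
    max_mismatches: int,
    exclude: Tuple[str, int] = None,
) -> List[Tuple[str, int, int]]:
    """Loop every window of every transcript, count mismatches explicitly.

    ``exclude`` is (transcript_id, start) of the intended site. Returns
    (transcript_id, start, mismatches) sorted by (transcript_id, start).
    """
    k = len(sense_kmer)
    hits = []
    for tid, seq in transcripts:
        for start in range(len(seq) - k + 1):
            mism = 0
            window = seq[start : start + k]
            for i in range(k):
                if window[i] != sense_kmer[i]:
                    mism += 1
                    if mism > max_mismatches:
                        break
            if mism <= max_mismatches:
                if exclude is not None and (tid, start) == exclude:
                    continue
                hits.append((tid, start, mism))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits
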