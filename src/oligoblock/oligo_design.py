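"""Candidate tiling, off-target screening, melting temperature and selection.

The design rule implemented here: tile every antisense k-mer across the
design window, discard candidates with transcriptome off-targets within the
mismatch budget (falling back to the lowest off-target count if none are
clean), and pick the highest-melting-temperature survivor.

Melting temperatures come from a two-state nearest-neighbor model: unified
DNA/DNA stack parameters plus per-position LNA perturbation increments, an
oligo-concentration term and a monovalent-salt correction (Owczarzy et al.
2004). Parameter tables are shipped as versioned JSON files with citations
(``oligoblock/data/``). 2'-O-methyl and 2'-methoxy-ethoxy chemistries have
no shipped thermodynamic tables; they are representable patterns whose Tm
can only be reported as a flagged heuristic estimate.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError, InputError, ThermoModelError
from .sequence_model import Interval, Transcriptome, reverse_complement
from .target_finder import DesignWindow, PolyASite, design_window, find_internal_polya, fragment_window

log = logging.getLogger(__name__)

GAS_CONSTANT = 1.987  # cal / (mol K)

DNA, LNA, OME, MOE = "DNA", "LNA", "OME", "MOE"
CHEMISTRIES = (DNA, LNA, OME, MOE)

PATTERN_PRESETS = (
    "all_dna",
    "full_lna",
    "alternating_lna",
    "full_ome",
    "alternating_ome",
    "full_moe",
    "alternating_moe",
)


@dataclass(frozen=True)
class ModificationPattern:
    """Per-position chemistry vector; alternating presets start modified."""

    chemistries: Tuple[str, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        for c in self.chemistries:
            if c not in CHEMISTRIES:
                raise ConfigError(f"unknown chemistry {c!r}")

    def __len__(self) -> int:
        return len(self.chemistries)

    @property
    def has_thermo_model(self) -> bool:
        return all(c in (DNA, LNA) for c in self.chemistries)

    @property
    def modified_positions(self) -> Tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.chemistries) if c != DNA)

    @classmethod
    def from_name(cls, name: str, length: int) -> "ModificationPattern":
        if name == "all_dna":
            chems: Tuple[str, ...] = (DNA,) * length
        elif name.startswith("full_"):
            chem = name[5:].upper()
            if chem not in CHEMISTRIES:
                raise ConfigError(f"unknown pattern preset {name!r}")
            chems = (chem,) * length
        elif name.startswith("alternating_"):
            chem = name[12:].upper()
            if chem not in CHEMISTRIES:
                raise ConfigError(f"unknown pattern preset {name!r}")
            chems = tuple(chem if i % 2 == 0 else DNA for i in range(length))
        else:
            raise ConfigError(
                f"unknown pattern preset {name!r}; choose one of {PATTERN_PRESETS}"
            )
        return cls(chemistries=chems, name=name)


@dataclass(frozen=True)
class ThermoConditions:
    """Hybridization conditions for the two-state Tm computation.

    Defaults (0.25 uM oligo, 50 mM monovalent, no divalent) are printed in
    every report; selection depends only on the Tm ranking, which is robust
    to the condition choice.
    """

    oligo_concentration: float = 0.25e-6  # molar
    monovalent_salt: float = 0.05  # molar
    divalent_salt: float = 0.0  # molar

    def __post_init__(self) -> None:
        if self.oligo_concentration <= 0:
            raise ConfigError("oligo_concentration must be > 0")
        if self.monovalent_salt <= 0:
            raise ConfigError("monovalent_salt must be > 0")
        if self.divalent_salt < 0:
            raise ConfigError("divalent_salt must be >= 0")

    @property
    def effective_monovalent(self) -> float:
        """Divalent cations folded into a monovalent equivalent
        (von Ahsen et al. 2001: [Na+]eq = [Mon] + 120*sqrt([Mg2+] in mM), in mM)."""
        return self.monovalent_salt + 3.795 * math.sqrt(self.divalent_salt)


@dataclass(frozen=True)
class OffTargetHit:
    transcript_id: str
    position: Interval
    mismatches: int


@dataclass
class OligoCandidate:
    """An antisense k-mer with modification pattern, Tm and off-target hits.

    ``seq`` is the DNA-alphabet antisense oligo; ``target_site`` is its
    sense-strand footprint, so ``seq == reverse_complement(sense k-mer)``.
    """

    seq: str
    target_site: Interval
    pattern: ModificationPattern
    tm_celsius: Optional[float] = None
    tm_is_estimate: bool = False
    offtargets: Optional[List[OffTargetHit]] = None
    rank_metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "N" in self.seq:
            raise InputError("candidate oligos may not contain N")
        if len(self.pattern) != len(self.seq):
            raise InputError("modification pattern length must equal oligo length")

    @property
    def k(self) -> int:
        return len(self.seq)

    @property
    def n_offtargets(self) -> int:
        return len(self.offtargets) if self.offtargets is not None else 0


# ---------------------------------------------------------------------------
# thermodynamics


def _load_table(filename: str) -> dict:
    with resources.files("oligoblock.data").joinpath(filename).open() as fh:
        return json.load(fh)


_DNA_TABLE = _load_table("nn_dna_unified.json")
_LNA_TABLE = _load_table("lna_increments.json")

PARAMETER_TABLE_VERSIONS = {
    _DNA_TABLE["name"]: _DNA_TABLE["version"],
    _LNA_TABLE["name"]: _LNA_TABLE["version"],
}

_NN = {k: (v["dH"], v["dS"]) for k, v in _DNA_TABLE["stacks"].items()}
_INIT_GC = (
    _DNA_TABLE["initiation"]["terminal_GC"]["dH"],
    _DNA_TABLE["initiation"]["terminal_GC"]["dS"],
)
_INIT_AT = (
    _DNA_TABLE["initiation"]["terminal_AT"]["dH"],
    _DNA_TABLE["initiation"]["terminal_AT"]["dS"],
)
_LNA_NN = {k: (v["ddH"], v["ddS"]) for k, v in _LNA_TABLE["stacks"].items()}
CONSECUTIVE_LNA_ATTENUATION = float(_LNA_TABLE["consecutive_attenuation"])


def duplex_thermodynamics(
    sense_bound_oligo: str,
    lna_mask: Sequence[bool],
    consecutive_attenuation: float = CONSECUTIVE_LNA_ATTENUATION,
) -> Tuple[float, float]:
    """Total (dH kcal/mol, dS cal/mol/K) for an oligo:complement duplex.

    Each LNA residue perturbs both adjacent stacks; a stack flanked by two
    LNA residues receives weight ``1 + consecutive_attenuation`` rather than
    2, reflecting the documented non-additivity of contiguous LNA runs.
    """
    seq = sense_bound_oligo
    if len(seq) < 2:
        raise InputError("need at least a dinucleotide for the two-state model")
    if len(lna_mask) != len(seq):
        raise InputError("lna_mask length must equal sequence length")
    dh = 0.0
    ds = 0.0
    for i in range(len(seq) - 1):
        stack = seq[i : i + 2]
        try:
            h, s = _NN[stack]
        except KeyError:
            raise InputError(f"no nearest-neighbor parameters for stack {stack!r}")
        dh += h
        ds += s
        n_mod = int(bool(lna_mask[i])) + int(bool(lna_mask[i + 1]))
        if n_mod:
            weight = 1.0 if n_mod == 1 else 1.0 + consecutive_attenuation
            ddh, dds = _LNA_NN[stack]
            dh += weight * ddh
            ds += weight * dds
    for terminal in (seq[0], seq[-1]):
        h, s = _INIT_GC if terminal in "GC" else _INIT_AT
        dh += h
        ds += s
    return dh, ds


def melting_temperature(
    candidate: "OligoCandidate | str",
    conditions: Optional[ThermoConditions] = None,
    pattern: Optional[ModificationPattern] = None,
) -> float:
    """Two-state nearest-neighbor melting temperature in degrees Celsius.

    Accepts an :class:`OligoCandidate` or a raw oligo sequence plus an
    optional pattern (all-DNA if omitted). Only DNA/LNA chemistries have a
    thermodynamic model; OME/MOE patterns raise :class:`ThermoModelError`
    directing the user to :func:`approximate_tm`.
    """
    conditions = conditions or ThermoConditions()
    if isinstance(candidate, OligoCandidate):
        seq = candidate.seq
        pattern = candidate.pattern
    else:
        seq = candidate.upper().replace("U", "T")
        if pattern is None:
            pattern = ModificationPattern.from_name("all_dna", len(seq))
    if "N" in seq:
        raise InputError("cannot compute Tm for sequences containing N")
    if not pattern.has_thermo_model:
        raise ThermoModelError(
            "no thermodynamic model is shipped for 2'-O-methyl / 2'-methoxy-ethoxy "
            "chemistries; rank such designs with approximate_tm(), which applies a "
            "documented heuristic offset to the DNA-backbone Tm and flags the "
            "result as an estimate"
        )
    lna_mask = [c == LNA for c in pattern.chemistries]
    dh, ds = duplex_thermodynamics(seq, lna_mask)
    # two-state Tm at 1 M monovalent reference, non-self-complementary factor 4
    tm_ref = dh * 1000.0 / (ds + GAS_CONSTANT * math.log(conditions.oligo_concentration / 4.0))
    # Owczarzy et al. 2004 monovalent correction (eq. 22)
    na = conditions.effective_monovalent
    fgc = sum(c in "GC" for c in seq) / len(seq)
    inv_tm = (
        1.0 / tm_ref
        + (4.29 * fgc - 3.95) * 1e-5 * math.log(na)
        + 9.40e-6 * math.log(na) ** 2
    )
    return 1.0 / inv_tm - 273.15


# documented heuristic per-modification Tm offsets (degrees C) used only for
# chemistries without a shipped thermodynamic table; always flagged
HEURISTIC_TM_OFFSET_PER_MOD = {OME: 0.8, MOE: 1.0}


def approximate_tm(
    seq: str,
    pattern: ModificationPattern,
    conditions: Optional[ThermoConditions] = None,
) -> Tuple[float, bool]:
    """DNA-backbone Tm plus a heuristic per-modification offset.

    Returns ``(tm_celsius, is_estimate)``; ``is_estimate`` is True whenever a
    heuristic offset was applied. Used for OME/MOE patterns so that design
    reports can still record a rough ranking for those chemistries.
    """
    conditions = conditions or ThermoConditions()
    if pattern.has_thermo_model:
        return melting_temperature(seq, conditions, pattern), False
    dna_lna_chems = tuple(c if c in (DNA, LNA) else DNA for c in pattern.chemistries)
    base = melting_temperature(
        seq, conditions, ModificationPattern(dna_lna_chems, name="backbone")
    )
    offset = sum(
        HEURISTIC_TM_OFFSET_PER_MOD.get(c, 0.0) for c in pattern.chemistries
    )
    return base + offset, True


# ---------------------------------------------------------------------------
# tiling and screening


def tile_candidates(
    window: DesignWindow,
    k: int,
    pattern: str | ModificationPattern = "full_lna",
) -> List[OligoCandidate]:
    """One antisense candidate per start offset: exactly L - k + 1 designs,
    ordered 5'->3' along the sense window."""
    if not (12 <= k <= 30):
        raise ConfigError(f"oligo length k={k} outside the supported range [12, 30]")
    if len(window) < k:
        raise InputError(
            f"design window of length {len(window)} is shorter than k={k}"
        )
    if isinstance(pattern, str):
        pattern = ModificationPattern.from_name(pattern, k)
    if len(pattern) != k:
        raise InputError("pattern length must equal k")
    candidates = []
    base = window.interval.start
    for offset in range(len(window) - k + 1):
        sense = window.seq[offset : offset + k]
        candidates.append(
            OligoCandidate(
                seq=reverse_complement(sense),
                target_site=Interval(window.interval.transcript_id, base + offset, base + offset + k),
                pattern=pattern,
            )
        )
    return candidates


_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
_ENCODE[ord("N")] = 4  # never equal to any candidate base: conservative mismatch


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def screen_offtargets(
    candidate: OligoCandidate,
    transcriptome: Transcriptome,
    max_mismatches: int = 3,
    exclude: Optional[Interval] = None,
) -> List[OffTargetHit]:
    """Exhaustive sense-strand Hamming scan of the whole transcriptome.

    Every window of every transcript whose Hamming distance to the
    candidate's sense target k-mer is <= ``max_mismatches`` is reported,
    minus the excluded intended site. ``N`` in the transcriptome mismatches
    every candidate base. Transcripts shorter than the candidate are skipped
    with a logged notice. The vectorized scan is exact (position-wise
    comparison, no heuristic seeding), so results are identical to a
    brute-force all-windows scan.
    """
    if max_mismatches < 0:
        raise ConfigError("max_mismatches must be >= 0")
    sense = reverse_complement(candidate.seq)
    k = len(sense)
    enc_q = _encode(sense)
    hits: List[OffTargetHit] = []
    for rec in transcriptome:
        if len(rec.seq) < k:
            log.info(
                "screen_offtargets: skipping transcript %s (length %d < k=%d)",
                rec.id, len(rec.seq), k,
            )
            continue
        enc_t = _encode(rec.seq)
        n_windows = len(enc_t) - k + 1
        mism = np.zeros(n_windows, dtype=np.int32)
        for j in range(k):
            mism += enc_t[j : j + n_windows] != enc_q[j]
        for pos in np.flatnonzero(mism <= max_mismatches):
            iv = Interval(rec.id, int(pos), int(pos) + k)
            if exclude is not None and iv == exclude:
                continue
            hits.append(OffTargetHit(rec.id, iv, int(mism[pos])))
    hits.sort(key=lambda h: (h.transcript_id, h.position.start))
    return hits


# ---------------------------------------------------------------------------
# selection


@dataclass
class SelectionResult:
    selected: OligoCandidate
    fallback_used: bool  # lowest-off-target retention instead of zero-off-target
    retained: List[OligoCandidate]


def select_oligo(
    candidates: List[OligoCandidate],
    max_mismatches: int = 3,
    anchor_position: Optional[int] = None,
) -> SelectionResult:
    """Two-stage selection: retain off-target-free candidates (or, if none,
    the minimal-off-target-count set), then take the maximum-Tm survivor.

    Ties break by smaller off-target count, then by target position closest
    to ``anchor_position`` (the priming site / fragment 3' end), then
    leftmost, then lexicographically -- so the result is invariant under
    permutation of the candidate list.
    """
    if not candidates:
        raise InputError("select_oligo: empty candidate list")
    for c in candidates:
        if c.offtargets is None:
            raise InputError(f"candidate {c.seq} has not been screened")
        if c.tm_celsius is None:
            raise InputError(f"candidate {c.seq} has no melting temperature")
    min_off = min(c.n_offtargets for c in candidates)
    fallback = min_off > 0
    retained = [c for c in candidates if c.n_offtargets == min_off]

    def sort_key(c: OligoCandidate):
        dist = (
            abs(anchor_position - c.target_site.end)
            if anchor_position is not None
            else 0
        )
        return (-c.tm_celsius, c.n_offtargets, dist, c.target_site.start, c.seq)

    selected = min(retained, key=sort_key)
    return SelectionResult(selected=selected, fallback_used=fallback, retained=retained)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class TargetSpec:
    """What to design against: a transcript id (polya mode) or a raw
    fragment sequence / transcript id (fragment mode)."""

    mode: str  # "polya" | "fragment"
    transcript_id: Optional[str] = None
    fragment_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("polya", "fragment"):
            raise InputError(f"unknown design mode {self.mode!r}")
        if self.mode == "polya" and not self.transcript_id:
            raise InputError("polya mode requires a transcript id")
        if self.mode == "fragment" and not (self.fragment_seq or self.transcript_id):
            raise InputError("fragment mode requires a fragment sequence or transcript id")


@dataclass
class DesignConfig:
    k: int = 16
    max_mismatches: int = 3
    pattern: str = "full_lna"
    width: int = 50
    min_run: int = 8
    min_a_fraction: float = 0.8
    tail_exclusion: int = 30
    conditions: ThermoConditions = field(default_factory=ThermoConditions)

    def to_dict(self) -> Dict:
        return {
            "k": self.k,
            "max_mismatches": self.max_mismatches,
            "pattern": self.pattern,
            "width": self.width,
            "min_run": self.min_run,
            "min_a_fraction": self.min_a_fraction,
            "tail_exclusion": self.tail_exclusion,
            "conditions": {
                "oligo_concentration_molar": self.conditions.oligo_concentration,
                "monovalent_salt_molar": self.conditions.monovalent_salt,
                "divalent_salt_molar": self.conditions.divalent_salt,
            },
        }


REPORT_COLUMNS_FIXED = [
    "window_id",
    "candidate_seq",
    "target_transcript",
    "start",
    "end",
    "start_1based",
    "end_1based",
    "pattern",
    "tm_c",
    "tm_is_estimate",
    "n_offtargets",
    "retained",
    "selected",
    "fallback_retention",
]


@dataclass
class DesignReport:
    rows: List[Dict]
    selections: List[OligoCandidate]
    provenance: Dict

    def columns(self) -> List[str]:
        max_mm = self.provenance["config"]["max_mismatches"]
        cols = list(REPORT_COLUMNS_FIXED)
        idx = cols.index("n_offtargets")
        for mm in range(max_mm + 1):
            cols.insert(idx, f"n_offtargets_mm{mm}")
            idx += 1
        return cols

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        cols = self.columns()
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in self.rows:
                fh.write("\t".join(_fmt(row.get(c)) for c in cols) + "\n")

    def to_json(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "provenance": self.provenance,
            "selections": [
                {
                    "candidate_seq": c.seq,
                    "target_transcript": c.target_site.transcript_id,
                    "start": c.target_site.start,
                    "end": c.target_site.end,
                    "tm_c": c.tm_celsius,
                    "tm_is_estimate": c.tm_is_estimate,
                    "n_offtargets": c.n_offtargets,
                }
                for c in self.selections
            ],
            "candidates": self.rows,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return f"{value:.3f}"
    return str(value)


def design_pipeline(
    target_spec: TargetSpec,
    transcriptome: Transcriptome,
    config: Optional[DesignConfig] = None,
) -> DesignReport:
    """find sites -> windows -> tile -> screen -> score -> select.

    polya mode yields one selected oligo per internal poly(A) site; a
    transcript with zero sites yields an empty report (with a warning).
    """
    config = config or DesignConfig()
    windows: List[DesignWindow] = []
    if target_spec.mode == "polya":
        transcript = transcriptome.get(target_spec.transcript_id)
        sites = find_internal_polya(
            transcript,
            min_run=config.min_run,
            min_a_fraction=config.min_a_fraction,
            tail_exclusion=config.tail_exclusion,
        )
        if not sites:
            log.warning(
                "no internal poly(A) sites found on %s; empty design report",
                transcript.id,
            )
        for site in sites:
            windows.append(design_window(site, transcript, width=config.width))
    else:
        if target_spec.fragment_seq:
            windows.append(fragment_window(target_spec.fragment_seq, k=config.k))
        else:
            transcript = transcriptome.get(target_spec.transcript_id)
            windows.append(
                fragment_window(
                    transcript.seq, k=config.k, transcript_id=transcript.id
                )
            )

    rows: List[Dict] = []
    selections: List[OligoCandidate] = []
    for w_idx, window in enumerate(windows):
        candidates = tile_candidates(window, config.k, config.pattern)
        for cand in candidates:
            exclude = (
                cand.target_site
                if cand.target_site.transcript_id in transcriptome
                else None
            )
            cand.offtargets = screen_offtargets(
                cand, transcriptome, config.max_mismatches, exclude=exclude
            )
            try:
                cand.tm_celsius = melting_temperature(cand, config.conditions)
                cand.tm_is_estimate = False
            except ThermoModelError:
                cand.tm_celsius, cand.tm_is_estimate = approximate_tm(
                    cand.seq, cand.pattern, config.conditions
                )
        result = select_oligo(
            candidates,
            max_mismatches=config.max_mismatches,
            anchor_position=window.interval.end,
        )
        selections.append(result.selected)
        retained_ids = {id(c) for c in result.retained}
        for cand in candidates:
            s1, e1 = cand.target_site.one_based()
            row = {
                "window_id": f"window_{w_idx + 1}",
                "candidate_seq": cand.seq,
                "target_transcript": cand.target_site.transcript_id,
                "start": cand.target_site.start,
                "end": cand.target_site.end,
                "start_1based": s1,
                "end_1based": e1,
                "pattern": cand.pattern.name,
                "tm_c": cand.tm_celsius,
                "tm_is_estimate": cand.tm_is_estimate,
                "n_offtargets": cand.n_offtargets,
                "retained": id(cand) in retained_ids,
                "selected": cand is result.selected,
                "fallback_retention": result.fallback_used,
            }
            for mm in range(config.max_mismatches + 1):
                row[f"n_offtargets_mm{mm}"] = sum(
                    1 for h in cand.offtargets if h.mismatches == mm
                )
            rows.append(row)

    from . import __version__

    provenance = {
        "tool": "oligoblock",
        "version": __version__,
        "mode": target_spec.mode,
        "target": target_spec.transcript_id or target_spec.fragment_seq,
        "config": config.to_dict(),
        "parameter_tables": PARAMETER_TABLE_VERSIONS,
        "n_windows": len(windows),
        "design_side_note": (
            "candidate windows are restricted to the 5' side of the priming "
            "site (the reverse-transcriptase extension direction)"
        ),
    }
    return DesignReport(rows=rows, selections=selections, provenance=provenance)
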