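"""Sliding-window uracil profiling and untranslatable-transcript design.

Membrane-protein mRNAs in *E. coli* carry ~60-nt U-rich stretches encoding
transmembrane helices.  To study protein binding to such RNAs independently
of translation, model transcripts are derived from real ORF segments but
made untranslatable: every start codon is destroyed, in-frame stop codons
are written periodically, and Shine-Dalgarno-like motifs are disrupted —
all while preserving the nucleotide (in particular U) composition that is
the putative recognition determinant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

SD_CONSENSUS = "AGGAGG"
_VALID = set("ACGT")


class AlphabetError(ValueError):
    """Raised for characters outside the unambiguous nucleotide alphabet."""


class DesignError(ValueError):
    """Raised when design constraints cannot be satisfied."""


def _normalize(sequence: str) -> str:
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - _VALID
    if bad:
        raise AlphabetError(f"non-ACGT/U characters in sequence: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class UProfile:
    """Windowed uracil-content profile of a nucleotide sequence."""

    positions: np.ndarray  # 0-based window start offsets
    u_fraction: np.ndarray  # T/U fraction per window, in [0, 1]
    window: int
    step: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "u_fraction": self.u_fraction})


def u_content_profile(sequence: str, window: int = 55, step: int = 1) -> UProfile:
    """Compute the sliding-window U (T) fraction of a sequence.

    Windows are 0-based and half-open: the window at position p covers
    sequence[p:p+window].  T and U are equivalent; case-insensitive.
    The 55-nt default matches the window length classically used to
    visualize U-rich transmembrane-helix-coding stretches.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    seq = _normalize(sequence)
    if len(seq) < window:
        raise ValueError(f"sequence length {len(seq)} shorter than window {window}")
    is_t = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("T")
    csum = np.concatenate([[0], np.cumsum(is_t)])
    starts = np.arange(0, len(seq) - window + 1, step)
    frac = (csum[starts + window] - csum[starts]) / window
    return UProfile(positions=starts, u_fraction=frac, window=window, step=step)


class Edit(NamedTuple):
    position: int
    old_base: str
    new_base: str
    reason: str  # start_removal | stop_insertion | sd_disruption


@dataclass(frozen=True)
class TranslatabilityReport:
    """Start/stop codon and SD-motif census of a sequence."""

    start_positions: dict[int, list[int]]  # frame -> 0-based positions
    stop_positions: dict[int, list[int]]
    sd_motifs: list[tuple[int, int]]  # maximal (start, end) SD-like matches
    sd_like_rbs: list[tuple[int, int]]  # (motif start, start-codon position)

    def start_codons(self, frame: int) -> int:
        return len(self.start_positions.get(frame, []))

    def stop_codons(self, frame: int) -> int:
        return len(self.stop_positions.get(frame, []))

    @property
    def start_codons_frame0(self) -> int:
        return self.start_codons(0)


def find_sd_motifs(sequence: str, min_match: int = 4) -> list[tuple[int, int]]:
    """Maximal intervals matching >=min_match consecutive bases of AGGAGG."""
    seq = _normalize(sequence)
    hits: list[tuple[int, int]] = []
    for length in range(len(SD_CONSENSUS), min_match - 1, -1):
        for off in range(len(SD_CONSENSUS) - length + 1):
            pat = SD_CONSENSUS[off : off + length]
            for m in re.finditer(f"(?={pat})", seq):
                iv = (m.start(), m.start() + length)
                if not any(iv[0] >= a and iv[1] <= b for a, b in hits):
                    hits.append(iv)
    return sorted(hits)


def verify_untranslatable(
    sequence: str,
    frames: Iterable[int] = (0, 1, 2),
    start_codons: Sequence[str] = ("ATG",),
    sd_spacer: tuple[int, int] = (4, 14),
) -> TranslatabilityReport:
    """Census start codons, stop codons and SD-like motifs per frame.

    An SD motif is flagged as RBS-like when the gap between its end and a
    downstream start codon (any scanned frame) lies within ``sd_spacer`` nt.
    Pure function; never modifies the sequence.
    """
    seq = _normalize(sequence)
    frames = sorted(set(frames))
    stops = {"TAA", "TAG", "TGA"}
    start_pos: dict[int, list[int]] = {f: [] for f in frames}
    stop_pos: dict[int, list[int]] = {f: [] for f in frames}
    for f in frames:
        for p in range(f, len(seq) - 2, 3):
            codon = seq[p : p + 3]
            if codon in start_codons:
                start_pos[f].append(p)
            elif codon in stops:
                stop_pos[f].append(p)
    motifs = find_sd_motifs(seq)
    all_starts = sorted(p for ps in start_pos.values() for p in ps)
    lo, hi = sd_spacer
    rbs = [
        (a, p)
        for a, b in motifs
        for p in all_starts
        if lo <= p - b <= hi
    ]
    return TranslatabilityReport(start_pos, stop_pos, motifs, rbs)


@dataclass(frozen=True)
class MimicDesign:
    """An untranslatable mimic of an ORF segment plus its edit log."""

    source_sequence: str
    mimic_sequence: str
    edits: list[Edit] = field(default_factory=list)
    report: TranslatabilityReport | None = None

    def __post_init__(self) -> None:
        if len(self.mimic_sequence) != len(self.source_sequence):
            raise ValueError("mimic and source must have equal length")


_BASE_ORDER = "TACG"  # fixed candidate order: reproducibility over optimality


def _creates_start(seq: list[str], i: int, frames: set[int], starts: Sequence[str]) -> bool:
    for p in range(max(0, i - 2), min(len(seq) - 2, i) + 1):
        if p % 3 in frames and "".join(seq[p : p + 3]) in starts:
            return True
    return False


def _sd_count_near(seq: list[str], a: int, b: int) -> int:
    lo, hi = max(0, a - 5), min(len(seq), b + 5)
    return len(find_sd_motifs("".join(seq[lo:hi])))


_HALF_WINDOW = 27  # half the 55-nt profiling window


def _local_imbalance(edits: Sequence["Edit"], pos: int) -> int:
    """Net T-count change of prior edits within half a profiling window."""
    return sum(
        (e.new_base == "T") - (e.old_base == "T")
        for e in edits
        if abs(e.position - pos) <= _HALF_WINDOW
    )


def _substitute(
    seq: list[str],
    positions: Sequence[int],
    frames: set[int],
    starts: Sequence[str],
    protected: set[int],
    edits: Sequence["Edit"],
    sd_interval: tuple[int, int] | None = None,
) -> tuple[int, str, str] | None:
    """Pick the (position, base) substitution that leaves no start codon at
    the touched positions and minimizes the local net T-count imbalance, so
    the windowed U profile of the mimic tracks the source.  Ties fall back
    to a fixed enumeration order (position, then T/A/C/G) for
    reproducibility.  When ``sd_interval`` is given the substitution must
    also reduce the number of SD-like motifs around that interval."""
    before = _sd_count_near(seq, *sd_interval) if sd_interval else 0
    best: tuple[int, int, int, str, str] | None = None
    order = 0
    for i in positions:
        if i in protected:
            continue
        old = seq[i]
        imb = _local_imbalance(edits, i)
        for new in _BASE_ORDER:
            if new == old:
                continue
            seq[i] = new
            ok = not _creates_start(seq, i, frames, starts)
            if ok and sd_interval:
                ok = _sd_count_near(seq, *sd_interval) < before
            seq[i] = old
            order += 1
            if ok:
                dt = (new == "T") - (old == "T")
                key = (abs(imb + dt), order)
                if best is None or key < best[:2]:
                    best = (*key, i, old, new)
    if best is None:
        return None
    return best[2], best[3], best[4]


def design_untranslatable_mimic(
    orf_segment: str,
    stop_period_codons: int = 15,
    frames_scanned: Iterable[int] = (0, 1, 2),
    start_codons: Sequence[str] = ("ATG",),
    stop_codon: str = "TAA",
) -> MimicDesign:
    """Turn an ORF segment into an untranslatable mimic.

    The mimic has the same length and near-identical U composition as the
    source but (1) carries no start codon in any scanned frame, each start
    destroyed by a single-base substitution that creates no new start,
    (2) carries a stop codon in frame 0 every ``stop_period_codons`` codons
    (first at codon index stop_period_codons - 1), and (3) has every
    Shine-Dalgarno-like motif (>=4-base match to AGGAGG) disrupted by one
    substitution.  Every changed base is logged in ``edits``.
    """
    source = _normalize(orf_segment)
    if len(source) % 3 != 0:
        raise DesignError(f"segment length {len(source)} not divisible by 3")
    if stop_period_codons < 1:
        raise DesignError("stop_period_codons must be >= 1")
    frames = set(frames_scanned)
    seq = list(source)
    n_codons = len(seq) // 3
    edits: list[Edit] = []

    # Periodic stop decoration in frame 0; positions become immutable.
    protected: set[int] = set()
    for c in range(stop_period_codons - 1, n_codons, stop_period_codons):
        p = 3 * c
        for k, base in enumerate(stop_codon):
            protected.add(p + k)
            if seq[p + k] != base:
                edits.append(Edit(p + k, seq[p + k], base, "stop_insertion"))
                seq[p + k] = base

    # Iterate start removal and SD disruption to a fixpoint: a stop or SD
    # edit can in principle expose a new start in another frame.
    for _ in range(100):
        report = verify_untranslatable("".join(seq), frames, start_codons)
        start_hits = sorted(p for f in frames for p in report.start_positions.get(f, []))
        sd_hits = report.sd_motifs
        if not start_hits and not sd_hits:
            break
        progressed = False
        for p in start_hits:
            if "".join(seq[p : p + 3]) not in start_codons:
                continue  # already destroyed by an earlier edit this pass
            pick = _substitute(seq, range(p, p + 3), frames, start_codons, protected, edits)
            if pick is None:
                raise DesignError(f"cannot destroy start codon at position {p}")
            i, old, new = pick
            seq[i] = new
            edits.append(Edit(i, old, new, "start_removal"))
            progressed = True
        for a, b in sd_hits:
            if not find_sd_motifs("".join(seq[max(0, a - 5) : min(len(seq), b + 5)])):
                continue
            mid = (a + b) // 2  # breaking the middle base kills all >=4 matches
            order = sorted(range(a, b), key=lambda i: (abs(i - mid), i))
            pick = _substitute(seq, order, frames, start_codons, protected, edits, (a, b))
            if pick is None:
                raise DesignError(f"cannot disrupt SD-like motif at {a}:{b}")
            i, old, new = pick
            seq[i] = new
            edits.append(Edit(i, old, new, "sd_disruption"))
            progressed = True
        if not progressed:
            raise DesignError("design did not converge: constraints unsatisfiable")
    else:
        raise DesignError("design did not converge within iteration limit")

    mimic = "".join(seq)
    return MimicDesign(
        source_sequence=source,
        mimic_sequence=mimic,
        edits=edits,
        report=verify_untranslatable(mimic, frames, start_codons),
    )
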