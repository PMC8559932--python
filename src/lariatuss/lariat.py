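"""Branch-point calling from lariat RT-PCR derived reads.

Reverse transcription around an intron lariat crosses the 2',5' bond, so a
sense-oriented cDNA read is an intron segment ending at the branch point
(BP) followed immediately by the intron's 5' terminus; the branch adenosine
is frequently misread as T.  The caller searches every read orientation,
split position and candidate BP for the decomposition

    read[0:k]  ==  intron segment ending at the BP   (pre-jump anchor)
    read[k:]   ==  intron prefix starting at base 1  (post-jump anchor)

maximizing matched bases, where a mismatch at the BP itself is free iff the
reference base is A and the read shows T (the signature); at a non-A BP the
junction base must match exactly, so non-A branch nucleotides remain
callable.  A call requires both anchors >= min_anchor and at most
max_mismatch mismatches outside the BP.  Ties between distinct BP
positions are first broken toward the longer exact prefix match of the
post-jump anchor, then the remaining co-optimal candidates make the call
ambiguous, reported with the 3'-most candidate first.

BP positions are reported as negative offsets from the intron's 3' end
(-1 = last intron base), the convention used for labels like "-25A"; labels
display T as U (RNA).
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import revcomp

CALLED = "called"
AMBIGUOUS = "ambiguous"
UNALIGNABLE = "unalignable"


@dataclass
class IntronRef:
    """An intron sequence in sense orientation, 5' -> 3' from base 1.

    Optional primer intervals (0-based half-open, within the intron) bound
    the anchor lengths that the amplicon design can produce; they are
    carried as metadata and used by the simulator.
    """

    intron_id: str
    sequence: str
    primers: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        for name, (s, e) in self.primers.items():
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError(f"{self.intron_id}: primer {name} interval outside intron")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def offset_to_index(self, bp_offset: int) -> int:
        """Negative 3'-anchored offset -> 0-based index (offset -1 = last base)."""
        if not -self.length <= bp_offset <= -1:
            raise ValueError(f"bp_offset {bp_offset} out of range for length {self.length}")
        return self.length + bp_offset

    def base_at(self, bp_offset: int) -> str:
        return self.sequence[self.offset_to_index(bp_offset)]


def label_bp(bp_offset: int, intron_ref: IntronRef) -> str:
    """Display label such as "-25A" or "-54U" (T shown as U, RNA convention)."""
    base = intron_ref.base_at(bp_offset)
    return f"{bp_offset}{'U' if base == 'T' else base}"


def parse_bp_label(label: str) -> tuple[int, str]:
    """Inverse of label_bp: "-54U" -> (-54, "T")."""
    offset, base = int(label[:-1]), label[-1].upper()
    return offset, "T" if base == "U" else base


@dataclass
class BranchPointCall:
    read_id: str
    intron_id: str
    status: str
    bp_offset: int | None = None
    bp_ref_base: str | None = None
    observed_base_at_bp: str | None = None
    a_to_t_signature: bool = False
    anchor_pre: int | None = None
    anchor_post: int | None = None
    mismatches: int | None = None
    orientation: str | None = None  # "as-is" | "reverse-complement"
    alternatives: tuple[int, ...] = ()  # co-optimal BP offsets when ambiguous


def _candidates(read: str, intron: str, min_anchor: int, max_mismatch: int):
    """All valid (mismatches, prefix_exact, bp_index, k, signature) splits of
    one read orientation.  bp_index is 0-based; k is the pre-jump length."""
    Lr, Li = len(read), len(intron)
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    s = np.frombuffer(intron.encode(), dtype=np.uint8)
    match = r[:, None] == s[None, :]
    # diag[i, j] = matches of read[0:i+1] aligned so read[i] sits on intron[j]
    diag = np.zeros_like(match, dtype=np.int32)
    diag[0] = match[0]
    for i in range(1, Lr):
        diag[i, 0] = match[i, 0]
        diag[i, 1:] = diag[i - 1, :-1] + match[i, 1:]
    is_a = s == ord("A")
    out = []
    for k in range(min_anchor, Lr - min_anchor + 1):
        L2 = Lr - k
        if L2 > Li or k > Li:
            continue
        post = r[k:] == s[:L2]
        post_mm = int(L2 - post.sum())
        prefix_exact = int(post.argmin()) if not post.all() else L2
        obs = read[k - 1]
        j = np.arange(k - 1, Li)  # candidate BP indices
        bp_match = match[k - 1, j]
        signature = (~bp_match) & is_a[j] & (obs == "T")
        valid_bp = bp_match | signature
        pre_mm = (k - 1) - (diag[k - 1, j] - bp_match)
        mm = pre_mm + post_mm
        ok = valid_bp & (mm <= max_mismatch)
        for idx in np.flatnonzero(ok):
            out.append((int(mm[idx]), prefix_exact, int(j[idx]), k, bool(signature[idx])))
    return out


def call_branchpoint(
    read_id: str,
    read_seq: str,
    intron_ref: IntronRef,
    min_anchor: int = 8,
    max_mismatch: int = 1,
) -> BranchPointCall:
    """Locate the BP-to-5'-terminus junction in one lariat-derived read.

    Both the read and its reverse complement are searched (cloning
    orientation is arbitrary).  Returns a called, ambiguous or unalignable
    BranchPointCall; ambiguous calls carry the co-optimal alternatives.
    """
    read_seq = read_seq.upper()
    intron = intron_ref.sequence
    if len(read_seq) < 2 * min_anchor:
        return BranchPointCall(read_id, intron_ref.intron_id, UNALIGNABLE)
    pool = []
    for orientation, seq in (("as-is", read_seq), ("reverse-complement", revcomp(read_seq))):
        for mm, prefix_exact, j, k, sig in _candidates(seq, intron, min_anchor, max_mismatch):
            pool.append((mm, -prefix_exact, -j, k, orientation, sig, seq))
    if not pool:
        return BranchPointCall(read_id, intron_ref.intron_id, UNALIGNABLE)
    best_mm = min(c[0] for c in pool)
    pool = [c for c in pool if c[0] == best_mm]
    best_prefix = min(c[1] for c in pool)
    pool = [c for c in pool if c[1] == best_prefix]
    pool.sort(key=lambda c: (c[2], c[3], c[4]))  # 3'-most BP first, stable
    distinct_bp = sorted({-c[2] for c in pool}, reverse=True)
    mm, _negpref, negj, k, orientation, sig, seq = pool[0]
    j = -negj
    status = CALLED if len(distinct_bp) == 1 else AMBIGUOUS
    Li = len(intron)
    return BranchPointCall(
        read_id=read_id,
        intron_id=intron_ref.intron_id,
        status=status,
        bp_offset=j - Li,
        bp_ref_base=intron[j],
        observed_base_at_bp=seq[k - 1],
        a_to_t_signature=sig,
        anchor_pre=k,
        anchor_post=len(seq) - k,
        mismatches=mm,
        orientation=orientation,
        alternatives=tuple(b - Li for b in distinct_bp[1:]),
    )


def call_reads(
    reads: Iterable[tuple[str, str]],
    intron_ref: IntronRef,
    min_anchor: int = 8,
    max_mismatch: int = 1,
) -> list[BranchPointCall]:
    return [call_branchpoint(rid, seq, intron_ref, min_anchor, max_mismatch) for rid, seq in reads]


@dataclass
class BPUsageTable:
    """Per-strain branch-point usage frequencies over called reads."""

    intron_id: str
    strain: str
    table: pd.DataFrame  # bp_offset, bp_ref_base, label, count, frequency
    n_called: int
    n_ambiguous: int
    n_unalignable: int

    def frequencies(self) -> dict[int, float]:
        return dict(zip(self.table["bp_offset"], self.table["frequency"]))


def aggregate_bp(calls: Sequence[BranchPointCall], intron_ref: IntronRef, strain: str) -> BPUsageTable:
    """Tally called reads per distinct (bp_offset, reference base).

    Frequencies are computed over called reads only; ambiguous and
    unalignable reads are tallied separately, never silently dropped.
    """
    ids = {c.intron_id for c in calls}
    if ids and ids != {intron_ref.intron_id}:
        raise ValueError(f"calls from multiple introns: {sorted(ids)}")
    called = [c for c in calls if c.status == CALLED]
    n_amb = sum(c.status == AMBIGUOUS for c in calls)
    n_un = sum(c.status == UNALIGNABLE for c in calls)
    counts: dict[tuple[int, str], int] = {}
    for c in called:
        key = (c.bp_offset, c.bp_ref_base)
        counts[key] = counts.get(key, 0) + 1
    rows = []
    for (off, base) in sorted(counts):
        n = counts[(off, base)]
        rows.append((off, base, label_bp(off, intron_ref), n, n / len(called)))
    table = pd.DataFrame(rows, columns=["bp_offset", "bp_ref_base", "label", "count", "frequency"])
    return BPUsageTable(intron_ref.intron_id, strain, table, len(called), n_amb, n_un)


def calls_to_frame(calls: Sequence[BranchPointCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            (
                c.read_id,
                c.intron_id,
                c.status,
                c.bp_offset,
                c.bp_ref_base,
                c.observed_base_at_bp,
                c.a_to_t_signature,
                c.anchor_pre,
                c.anchor_post,
                c.mismatches,
                c.orientation,
                ",".join(map(str, c.alternatives)),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "intron_id",
            "status",
            "bp_offset",
            "bp_ref_base",
            "observed_base_at_bp",
            "a_to_t_signature",
            "anchor_pre",
            "anchor_post",
            "mismatches",
            "orientation",
            "alternatives",
        ],
    )
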