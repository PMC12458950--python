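"""Clone-tag recovery from barcoded sequencing reads.

Each lentiviral barcode is transcribed into the 3' UTR of a marker mRNA, so
reads covering the transcript contain (part of) the 265-nt semi-random
barcode followed by a fixed 33-nt stretch of vector backbone. The extractor
scans each read for that anchor (tolerating a few mismatches, on either
strand), takes the 15 bases abutting the anchor as the clone tag, collapses
sequencing-error tags into their abundant parents, and tabulates per-cell
tag support. All coordinates are 0-based, half-open.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Optional

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_ANCHOR",
    "MULTIPLET",
    "UNASSIGNED",
    "ReadRecord",
    "AnchorConfig",
    "AnchorHit",
    "ExtractionResult",
    "revcomp",
    "locate_anchor",
    "extract_clone_tag",
    "correct_tags",
    "build_cell_clone_table",
    "assign_clones",
    "reconstruct_full_barcode",
]

# Fixed 3' vector-backbone sequence immediately downstream of the barcode.
DEFAULT_ANCHOR = "CAGATCTTAGCCACTTTTTAAAAGAAAAGGGGG"

MULTIPLET = "MULTIPLET"
UNASSIGNED = "UNASSIGNED"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read, optionally with droplet cell tag and UMI."""

    read_id: str
    sequence: str
    cell_tag: Optional[str] = None
    umi: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id}: empty sequence")
        for label, val in (("cell_tag", self.cell_tag), ("umi", self.umi)):
            if val is not None and (set(val) - set("ACGTN")):
                raise ValueError(f"read {self.read_id}: {label} not over ACGTN")


@dataclass(frozen=True)
class AnchorConfig:
    """How to locate the anchor and cut the clone tag out of a read.

    ``tag_side="before_anchor"`` reads the tag as the barcode's 3' terminus
    abutting the downstream vector anchor (the default orientation);
    ``"after_anchor"`` takes the bases immediately following the anchor
    instead. ``scan_revcomp`` also searches the reverse complement, since
    library reads arrive in both orientations.
    """

    anchor: str = DEFAULT_ANCHOR
    max_mismatch: int = 2
    tag_len: int = 15
    tag_side: str = "before_anchor"
    scan_revcomp: bool = True

    def __post_init__(self) -> None:
        if set(self.anchor) - set("ACGT"):
            raise ValueError("anchor must be over ACGT")
        if self.tag_len < 1:
            raise ValueError("tag_len must be >= 1")
        if self.max_mismatch < 0 or self.max_mismatch >= len(self.anchor) / 4:
            raise ValueError("max_mismatch must satisfy 0 <= m < anchor_len/4")
        if self.tag_side not in ("before_anchor", "after_anchor"):
            raise ValueError("tag_side must be before_anchor or after_anchor")


class AnchorHit(NamedTuple):
    position: int  # 0-based start of the anchor, in anchor-strand orientation
    strand: str  # "+" or "-"
    mismatches: int


def _hamming_scan(seq: str, anchor: str) -> tuple[int, int] | None:
    """(position, mismatches) of the leftmost minimum-mismatch window."""
    la = len(anchor)
    if len(seq) < la:
        return None
    # Exact hit is always optimal and str.find returns the leftmost one.
    pos = seq.find(anchor)
    if pos >= 0:
        return pos, 0
    s = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    a = np.frombuffer(anchor.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(s, la)
    mism = (windows != a).sum(axis=1)
    best = int(mism.argmin())  # argmin is leftmost on ties
    return best, int(mism[best])


def locate_anchor(sequence: str, config: AnchorConfig | None = None) -> Optional[AnchorHit]:
    """Best anchor placement in a read, or None.

    Both strands are scanned (forward first); the hit with fewest mismatches
    wins, ties going to the forward strand, and within a strand the leftmost
    minimum wins. For a "-" hit the reported position is the anchor start in
    the reverse-complemented read. Returns None when no window has at most
    ``max_mismatch`` mismatches (including reads shorter than the anchor).
    """
    config = config or AnchorConfig()
    sequence = sequence.upper()
    fwd = _hamming_scan(sequence, config.anchor)
    rev = _hamming_scan(revcomp(sequence), config.anchor) if config.scan_revcomp else None
    best: Optional[AnchorHit] = None
    if fwd is not None and fwd[1] <= config.max_mismatch:
        best = AnchorHit(fwd[0], "+", fwd[1])
    if rev is not None and rev[1] <= config.max_mismatch:
        if best is None or rev[1] < best.mismatches:
            best = AnchorHit(rev[0], "-", rev[1])
    return best


def _extract_with_reason(
    read: ReadRecord, config: AnchorConfig
) -> tuple[Optional[str], Optional[str], Optional[AnchorHit], Optional[str]]:
    """(tag, oriented_sequence, hit, failure_reason)."""
    hit = locate_anchor(read.sequence, config)
    if hit is None:
        return None, None, None, "no_anchor"
    oriented = read.sequence.upper() if hit.strand == "+" else revcomp(read.sequence.upper())
    if config.tag_side == "before_anchor":
        start = hit.position - config.tag_len
        if start < 0:
            return None, oriented, hit, "truncated"
        tag = oriented[start : hit.position]
    else:
        start = hit.position + len(config.anchor)
        tag = oriented[start : start + config.tag_len]
        if len(tag) < config.tag_len:
            return None, oriented, hit, "truncated"
    if "N" in tag:
        return None, oriented, hit, "ambiguous_base"
    return tag, oriented, hit, None


def extract_clone_tag(read: ReadRecord, config: AnchorConfig | None = None) -> Optional[str]:
    """The read's clone tag, or None (anchor absent, tag truncated, or N in tag)."""
    tag, _, _, _ = _extract_with_reason(read, config or AnchorConfig())
    return tag


def _hamming1_neighbors(tag: str) -> Iterator[str]:
    for i, c in enumerate(tag):
        for b in "ACGT":
            if b != c:
                yield tag[:i] + b + tag[i + 1 :]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def correct_tags(
    tag_counts: Mapping[str, int],
    max_hamming: int = 1,
    ratio: float = 2.0,
) -> tuple[dict[str, int], list[tuple[str, str, int]]]:
    """Directional-adjacency collapse of sequencing-error tags.

    Tag ``b`` is absorbed into tag ``a`` when hamming(a, b) <= ``max_hamming``
    and count(a) >= ratio * count(b) - 1, the asymmetry that distinguishes an
    error shadow from two genuinely co-abundant clones. Tags are processed
    from highest count down (ties broken lexicographically) and the pass is
    repeated until a fixed point, which makes the result independent of input
    order and idempotent. Total count is conserved.

    Returns the corrected counts and a merge log of
    ``(absorbed_tag, surviving_parent, absorbed_count)`` with parent chains
    fully resolved.
    """
    if not tag_counts:
        return {}, []
    lengths = {len(t) for t in tag_counts}
    if len(lengths) != 1:
        raise ValueError(f"tags must share one length, got lengths {sorted(lengths)}")
    if any(c < 1 for c in tag_counts.values()):
        raise ValueError("all counts must be >= 1")

    counts = dict(tag_counts)
    parent_of: dict[str, str] = {}
    while True:
        order = sorted(counts, key=lambda t: (-counts[t], t))
        kept: dict[str, int] = {}
        merged_any = False
        for tag in order:
            c = counts[tag]
            if max_hamming == 1:
                cands = [n for n in _hamming1_neighbors(tag) if n in kept]
            else:
                cands = [k for k in kept if _hamming(k, tag) <= max_hamming]
            cands = [a for a in cands if counts[a] >= ratio * c - 1]
            if cands:
                parent = max(cands, key=lambda a: (counts[a], a))
                kept[parent] += c
                parent_of[tag] = parent
                merged_any = True
            else:
                kept[tag] = kept.get(tag, 0) + c
        counts = kept
        if not merged_any:
            break

    def _resolve(tag: str) -> str:
        while tag in parent_of:
            tag = parent_of[tag]
        return tag

    log = sorted(
        (child, _resolve(child), tag_counts[child]) for child in parent_of
    )
    return counts, log


@dataclass
class ExtractionResult:
    """Cell x clone tag table plus extraction bookkeeping."""

    table: pd.DataFrame  # columns: cell_tag, clone_tag, read_count, umi_count
    n_reads: int = 0
    n_no_cell_tag: int = 0
    reason_counts: dict[str, int] = field(default_factory=dict)
    merge_log: list[tuple[str, str, int]] = field(default_factory=list)

    def tag_map(self) -> dict[str, str]:
        return {child: parent for child, parent, _ in self.merge_log}


def build_cell_clone_table(
    reads: Iterable[ReadRecord],
    config: AnchorConfig | None = None,
    correct: bool = True,
    max_hamming: int = 1,
    ratio: float = 2.0,
) -> ExtractionResult:
    """Extract, correct, and tabulate clone tags per cell.

    Error correction runs on tag counts pooled over all cells (an error tag's
    parent may sit in another cell), then corrected tags are tabulated per
    (cell_tag, clone_tag) with supporting read and distinct-UMI counts. Reads
    without a cell tag are counted but excluded from the table.
    """
    config = config or AnchorConfig()
    pooled: dict[str, int] = defaultdict(int)
    per_read: list[tuple[str, str, Optional[str]]] = []  # (cell, tag, umi)
    reasons: dict[str, int] = defaultdict(int)
    n_reads = 0
    n_no_cell = 0
    for read in reads:
        n_reads += 1
        tag, _, _, reason = _extract_with_reason(read, config)
        if tag is None:
            reasons[reason] += 1
            continue
        if read.cell_tag is None:
            n_no_cell += 1
            continue
        pooled[tag] += 1
        per_read.append((read.cell_tag, tag, read.umi))

    merge_log: list[tuple[str, str, int]] = []
    tag_map: dict[str, str] = {}
    if correct and pooled:
        _, merge_log = correct_tags(pooled, max_hamming=max_hamming, ratio=ratio)
        tag_map = {child: parent for child, parent, _ in merge_log}

    read_counts: dict[tuple[str, str], int] = defaultdict(int)
    umi_sets: dict[tuple[str, str], set[str]] = defaultdict(set)
    for cell, tag, umi in per_read:
        tag = tag_map.get(tag, tag)
        key = (cell, tag)
        read_counts[key] += 1
        if umi is not None:
            umi_sets[key].add(umi)

    rows = [
        (cell, tag, n, len(umi_sets.get((cell, tag), ())))
        for (cell, tag), n in sorted(read_counts.items())
    ]
    table = pd.DataFrame(
        rows, columns=["cell_tag", "clone_tag", "read_count", "umi_count"]
    )
    return ExtractionResult(
        table=table,
        n_reads=n_reads,
        n_no_cell_tag=n_no_cell,
        reason_counts=dict(reasons),
        merge_log=merge_log,
    )


def assign_clones(
    table: pd.DataFrame,
    min_umi: int = 2,
    multiplet_frac: float = 0.2,
) -> pd.DataFrame:
    """Call one clone per cell from its tag support.

    Candidate tags need at least ``min_umi`` distinct UMIs (read counts stand
    in when the table carries no UMIs at all). A cell with no candidate is
    UNASSIGNED; with one, that clone; with several, the dominant clone unless
    the runner-up reaches ``multiplet_frac`` of its support, which flags a
    MULTIPLET (two barcoded cells in one droplet, or a double integration).

    Returns a frame with columns cell_tag, assignment, support, second_support.
    """
    required = {"cell_tag", "clone_tag", "read_count", "umi_count"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    use_umis = bool((table["umi_count"] > 0).any())
    support_col = "umi_count" if use_umis else "read_count"
    rows = []
    for cell, sub in table.groupby("cell_tag", sort=True):
        sub = sub.sort_values(
            [support_col, "clone_tag"], ascending=[False, True]
        )
        support = sub[support_col].to_numpy()
        cands = sub[support >= min_umi]
        if len(cands) == 0:
            rows.append((cell, UNASSIGNED, 0, 0))
            continue
        top = cands.iloc[0]
        second = int(cands.iloc[1][support_col]) if len(cands) > 1 else 0
        if len(cands) > 1 and second / top[support_col] >= multiplet_frac:
            rows.append((cell, MULTIPLET, int(top[support_col]), second))
        else:
            rows.append((cell, top["clone_tag"], int(top[support_col]), second))
    return pd.DataFrame(
        rows, columns=["cell_tag", "assignment", "support", "second_support"]
    )


def reconstruct_full_barcode(
    reads: Iterable[ReadRecord],
    target_tag: str,
    config: AnchorConfig | None = None,
    barcode_len: int = 265,
) -> str:
    """Consensus full-length barcode for one clone by anchored majority vote.

    Reads whose extracted tag equals ``target_tag`` are aligned on their
    anchor coordinate; with ``tag_side="before_anchor"`` the barcode is the
    ``barcode_len`` bases ending at the anchor start, otherwise the bases
    following the anchor. Each covered position takes the simple majority
    base; ties and uncovered positions yield N.
    """
    config = config or AnchorConfig()
    votes = np.zeros((barcode_len, 4), dtype=np.int64)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    n_matching = 0
    for read in reads:
        tag, oriented, hit, _ = _extract_with_reason(read, config)
        if tag != target_tag:
            continue
        n_matching += 1
        if config.tag_side == "before_anchor":
            bc_start = hit.position - barcode_len  # may be negative: partial cover
        else:
            bc_start = hit.position + len(config.anchor)
        for j in range(barcode_len):
            i = bc_start + j
            if 0 <= i < len(oriented):
                b = oriented[i]
                if b in base_idx:
                    votes[j, base_idx[b]] += 1
    if n_matching == 0:
        raise ValueError(f"no read carries tag {target_tag}")
    bases = np.array(list("ACGT"))
    best = votes.max(axis=1)
    winner = votes.argmax(axis=1)
    unique_max = (votes == best[:, None]).sum(axis=1) == 1
    out = np.where((best > 0) & unique_max, bases[winner], "N")
    return "".join(out)
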