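"""STR-anchored pairwise alignment of ortholog amplicons.

STR regions with the same (rotation-equivalent, after harmonization) motif
are paired in order across species and used as alignment anchors: repeat
units align unit-by-unit within an anchor, with surplus repeats of the longer
array gapped as whole units at the block's right edge.  Flank segments
between anchors are aligned globally with affine gap penalties (match +1,
mismatch -1, gap open -3, gap extend -1).  Gaps are thereby kept outside STR
blocks, and all indels are read as insertions in the fragment that carries
the extra bases.

The quantity of interest downstream is the non-STR length imbalance: the
number of gap-opposed nucleotides outside every STR region, per species.
This is the portion of a fragment-length difference that calibration to
repeat numbers cannot see, and the mechanism by which length-based genotypes
overstate interspecies differentiation.

When a region is disrupted in one species (one array facing two arrays split
by a short interruption), the split side's sub-regions join the single
region's anchor group and the interruption bases count as species-specific
non-STR nucleotides.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .strdetect import DISRUPTION_GAP_NT
from .types import STRStructure, rotation_equivalent

GAP = "-"


def _flank_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    return aligner


@dataclass
class OrthologAlignment:
    """A gapped pairwise alignment of chimpanzee and human amplicons."""

    marker: str
    chimp_aln: str
    human_aln: str
    chimp_str_mask: np.ndarray  # bool per chimp sequence position
    human_str_mask: np.ndarray
    anchored: bool = True
    str_blocks: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.chimp_aln) != len(self.human_aln):
            raise ValueError("aligned strings differ in length")
        # per-position column indices and per-column sequence offsets
        self._chimp_cols = np.flatnonzero(np.frombuffer(
            self.chimp_aln.encode(), dtype="S1") != GAP.encode())
        self._human_cols = np.flatnonzero(np.frombuffer(
            self.human_aln.encode(), dtype="S1") != GAP.encode())
        ncol = len(self.chimp_aln)
        self._human_before = np.zeros(ncol + 1, dtype=int)
        self._chimp_before = np.zeros(ncol + 1, dtype=int)
        hc = np.frombuffer(self.human_aln.encode(), dtype="S1") != GAP.encode()
        cc = np.frombuffer(self.chimp_aln.encode(), dtype="S1") != GAP.encode()
        self._human_before[1:] = np.cumsum(hc)
        self._chimp_before[1:] = np.cumsum(cc)

    @property
    def chimp_seq(self) -> str:
        return self.chimp_aln.replace(GAP, "")

    @property
    def human_seq(self) -> str:
        return self.human_aln.replace(GAP, "")

    def map_interval(self, species_from: str, start: int, end: int) -> tuple[int, int]:
        """Project a 0-based half-open interval onto the other species' coordinates."""
        if species_from == "chimpanzee":
            cols, before = self._chimp_cols, self._human_before
        elif species_from == "human":
            cols, before = self._human_cols, self._chimp_before
        else:
            raise ValueError(f"unknown species {species_from!r}")
        if start >= end:
            return (0, 0)
        col_lo = cols[start]
        col_hi = cols[end - 1] + 1
        return int(before[col_lo]), int(before[col_hi])

    def species_specific_counts(self) -> tuple[int, int]:
        """(chimp_only_nonstr_nt, human_only_nonstr_nt): gap-opposed non-STR bases."""
        c_pos = h_pos = 0
        chimp_only = human_only = 0
        for c_ch, h_ch in zip(self.chimp_aln, self.human_aln):
            if c_ch != GAP and h_ch == GAP:
                if not self.chimp_str_mask[c_pos]:
                    chimp_only += 1
            elif h_ch != GAP and c_ch == GAP:
                if not self.human_str_mask[h_pos]:
                    human_only += 1
            if c_ch != GAP:
                c_pos += 1
            if h_ch != GAP:
                h_pos += 1
        return chimp_only, human_only

    @property
    def chimp_only_nonstr_nt(self) -> int:
        return self.species_specific_counts()[0]

    @property
    def human_only_nonstr_nt(self) -> int:
        return self.species_specific_counts()[1]


def _str_mask(structure: STRStructure, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for reg in structure.regions:
        mask[reg.start:reg.end] = True
    return mask


def _pair_anchors(chimp: STRStructure, human: STRStructure):
    """Order-preserving pairing of regions with rotation-equivalent motifs (LCS)."""
    cr, hr = chimp.regions, human.regions
    n, m = len(cr), len(hr)
    dp = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if (rotation_equivalent(cr[i].motif, hr[j].motif)
                    and cr[i].unit_size == hr[j].unit_size):
                dp[i, j] = 1 + dp[i + 1, j + 1]
            dp[i, j] = max(dp[i, j], dp[i + 1, j], dp[i, j + 1])
    pairs = []
    i = j = 0
    while i < n and j < m:
        if (rotation_equivalent(cr[i].motif, hr[j].motif)
                and cr[i].unit_size == hr[j].unit_size
                and dp[i, j] == 1 + dp[i + 1, j + 1]):
            pairs.append((i, j))
            i += 1
            j += 1
        elif dp[i + 1, j] >= dp[i, j + 1]:
            i += 1
        else:
            j += 1
    return pairs


def _group_disruptions(pairs, chimp: STRStructure, human: STRStructure):
    """Merge an unpaired region into the adjacent paired one when it looks like a split.

    Returns anchor groups [(chimp region indices, human region indices)], in order.
    """
    groups = [([c], [h]) for c, h in pairs]
    paired_c = {c for c, _ in pairs}
    paired_h = {h for _, h in pairs}

    def try_merge(regions, paired, axis):
        for idx, reg in enumerate(regions):
            if idx in paired:
                continue
            for g in groups:
                members = g[axis]
                for m in list(members):
                    anchor = regions[m]
                    if not (rotation_equivalent(reg.motif, anchor.motif)
                            and reg.unit_size == anchor.unit_size):
                        continue
                    gap = (reg.start - anchor.end if reg.start >= anchor.end
                           else anchor.start - reg.end)
                    if abs(idx - m) == 1 and 0 < gap <= DISRUPTION_GAP_NT:
                        members.append(idx)
                        members.sort()
                        paired.add(idx)
                        break
                else:
                    continue
                break

    try_merge(chimp.regions, paired_c, 0)
    try_merge(human.regions, paired_h, 1)
    groups.sort(key=lambda g: chimp.regions[g[0][0]].start)
    return groups


def _align_flank(a: str, b: str) -> tuple[str, str]:
    if not a and not b:
        return "", ""
    if not a:
        return GAP * len(b), b
    if not b:
        return a, GAP * len(a)
    alignment = _flank_aligner().align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def _emit_group(chimp_seq, human_seq, c_members, h_members, chimp, human):
    """Column strings for one anchor group (STR arrays plus any interruptions)."""
    def stream(regions, members, seq):
        # (bases, is_str) chunks covering the group's span on one species
        chunks = []
        members = sorted(members)
        for k, idx in enumerate(members):
            reg = regions[idx]
            if k > 0:
                prev = regions[members[k - 1]]
                chunks.append((seq[prev.end:reg.start], False))
            chunks.append((seq[reg.start:reg.end], True))
        return chunks

    c_queue = stream(chimp.regions, c_members, chimp_seq)
    h_queue = stream(human.regions, h_members, human_seq)
    buf_c, buf_h = [], []
    while c_queue or h_queue:
        # flush non-STR chunks first (interruption bases vs gaps)
        if c_queue and not c_queue[0][1]:
            bases, _ = c_queue.pop(0)
            buf_c.append(bases)
            buf_h.append(GAP * len(bases))
            continue
        if h_queue and not h_queue[0][1]:
            bases, _ = h_queue.pop(0)
            buf_h.append(bases)
            buf_c.append(GAP * len(bases))
            continue
        if c_queue and h_queue:
            cb, _ = c_queue.pop(0)
            hb, _ = h_queue.pop(0)
            k = min(len(cb), len(hb))
            buf_c.append(cb[:k])
            buf_h.append(hb[:k])
            if len(cb) > k:
                c_queue.insert(0, (cb[k:], True))
            if len(hb) > k:
                h_queue.insert(0, (hb[k:], True))
        elif c_queue:
            cb, _ = c_queue.pop(0)
            buf_c.append(cb)
            buf_h.append(GAP * len(cb))
        else:
            hb, _ = h_queue.pop(0)
            buf_h.append(hb)
            buf_c.append(GAP * len(hb))
    return "".join(buf_c), "".join(buf_h)


def align_orthologs(chimp_seq: str, human_seq: str,
                    chimp_structure: STRStructure, human_structure: STRStructure,
                    marker: str = "") -> OrthologAlignment:
    """Align two ortholog amplicons with STR regions as anchors.

    Falls back to a plain global alignment (``anchored=False``) when no STR
    anchors can be paired.
    """
    chimp_seq = chimp_seq.upper()
    human_seq = human_seq.upper()
    pairs = _pair_anchors(chimp_structure, human_structure)
    c_mask = _str_mask(chimp_structure, len(chimp_seq))
    h_mask = _str_mask(human_structure, len(human_seq))

    if not pairs:
        a, b = _align_flank(chimp_seq, human_seq)
        return OrthologAlignment(marker, a, b, c_mask, h_mask, anchored=False)

    groups = _group_disruptions(pairs, chimp_structure, human_structure)

    # verify group order is consistent on both species; else fall back
    h_starts = [min(human_structure.regions[i].start for i in g[1]) for g in groups]
    if h_starts != sorted(h_starts):
        a, b = _align_flank(chimp_seq, human_seq)
        return OrthologAlignment(marker, a, b, c_mask, h_mask, anchored=False)

    out_c, out_h = [], []
    c_pos = h_pos = 0
    blocks = []
    for c_members, h_members in groups:
        c_lo = min(chimp_structure.regions[i].start for i in c_members)
        c_hi = max(chimp_structure.regions[i].end for i in c_members)
        h_lo = min(human_structure.regions[i].start for i in h_members)
        h_hi = max(human_structure.regions[i].end for i in h_members)
        fa, fb = _align_flank(chimp_seq[c_pos:c_lo], human_seq[h_pos:h_lo])
        out_c.append(fa)
        out_h.append(fb)
        ga, gb = _emit_group(chimp_seq, human_seq, c_members, h_members,
                             chimp_structure, human_structure)
        out_c.append(ga)
        out_h.append(gb)
        blocks.append((tuple(c_members), tuple(h_members)))
        c_pos, h_pos = c_hi, h_hi
    fa, fb = _align_flank(chimp_seq[c_pos:], human_seq[h_pos:])
    out_c.append(fa)
    out_h.append(fb)
    return OrthologAlignment(marker, "".join(out_c), "".join(out_h),
                             c_mask, h_mask, anchored=True, str_blocks=blocks)


def nonstr_imbalance(alignment: OrthologAlignment) -> tuple[int, int]:
    """Species-specific non-STR nucleotide counts (chimp_only, human_only)."""
    return alignment.species_specific_counts()
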