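"""Motif-anchored detection of unannotated clade members in genomic sequence.

The strategy: translate the genome in all six frames, locate every
presence-called occurrence of the clade's first (N-terminal-most) and last
(C-terminal-most) motifs, and turn anchors into candidate proteins.  Paired
anchors in one reading frame delimit a window directly; a lone anchor is
extended to a target protein length (default 280 residues) using offsets
learned from the seed family's architecture.  Windows are clipped to the
stop-free translated segment containing the anchor, and candidates carrying
at least ``min_motifs`` (default 3) of the family motifs are called members.
Members are finally reconciled against existing annotation: >= 50% reciprocal
overlap on the same strand confirms an annotated gene, anything else is a
novel member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_core import GeneAnnotation, reverse_complement
from .motif_toolkit import MotifHit, MotifModel, architecture, call_presence, scan_protein

__all__ = [
    "TranslatedTrack",
    "CandidateParalog",
    "six_frame_translate",
    "find_anchors",
    "anchor_offsets_from_seeds",
    "build_candidates",
    "filter_members",
    "reconcile_with_annotation",
    "scan_genome",
]

_STOP_CODONS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate(dna: str) -> str:
    """Translate an in-frame nucleotide string; any codon containing N -> X."""
    out = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        codon = dna[i : i + 3]
        out.append("X" if "N" in codon else _CODON_TABLE[codon])
    return "".join(out)


@dataclass
class TranslatedTrack:
    """One reading frame of one sequence, with residue -> genome coordinates."""

    seq_id: str
    strand: str  # '+' or '-'
    frame: int  # 0, 1, 2
    protein: str  # includes '*' for stops
    seq_length: int

    def residue_interval(self, index: int) -> tuple[int, int]:
        """Forward-strand 0-based half-open interval of residue ``index``'s codon."""
        if self.strand == "+":
            start = self.frame + 3 * index
            return start, start + 3
        end = self.seq_length - self.frame - 3 * index
        return end - 3, end

    def span_interval(self, start_res: int, end_res: int) -> tuple[int, int]:
        """Forward-strand interval covering residues [start_res, end_res)."""
        first = self.residue_interval(start_res)
        last = self.residue_interval(end_res - 1)
        lo = min(first[0], last[0])
        hi = max(first[1], last[1])
        return lo, hi


def six_frame_translate(seq: str, seq_id: str = "") -> list[TranslatedTrack]:
    """All six translated tracks of a nucleotide sequence.

    Frames 0-2 on the forward strand and 0-2 on the reverse complement;
    stops are emitted as ``*`` and every residue maps back to its codon's
    forward-strand interval.
    """
    seq = seq.upper()
    tracks = []
    rc = reverse_complement(seq)
    for frame in range(3):
        tracks.append(
            TranslatedTrack(seq_id, "+", frame, translate(seq[frame:]), len(seq))
        )
    for frame in range(3):
        tracks.append(
            TranslatedTrack(seq_id, "-", frame, translate(rc[frame:]), len(seq))
        )
    return tracks


@dataclass(frozen=True)
class AnchorHit:
    """A presence-called anchor occurrence within one translated track."""

    track_index: int
    kind: str  # 'first' or 'last'
    res_start: int  # 0-based residue index in the track
    res_end: int  # exclusive
    genomic: tuple[int, int]
    logodds: float
    consensus_identity: float


def _presence_windows(
    protein: str, motif: MotifModel, identity_threshold: float
) -> list[tuple[int, float, float]]:
    """All windows that would be presence-called, as (start, logodds, identity).

    Unlike :func:`scan_protein` (best hit only), anchor search needs every
    qualifying occurrence: a genome track can contain several family members.
    Overlapping qualifying windows are greedily reduced to local score maxima.
    """
    width = motif.width
    if len(protein) < width:
        return []
    from .motif_toolkit import _encode, _RESIDUE_INDEX  # shared encoders

    encoded = _encode(protein)
    lo = motif.logodds()
    n_windows = len(protein) - width + 1
    cons = np.array([_RESIDUE_INDEX[c] for c in motif.consensus], dtype=np.intp)
    idx = encoded[np.arange(n_windows)[:, None] + np.arange(width)[None, :]]
    valid = idx >= 0
    scores = np.where(valid, lo[np.arange(width)[None, :], idx], 0.0).sum(axis=1)
    idents = (idx == cons).mean(axis=1)
    qualifying = np.flatnonzero((idents >= identity_threshold) & (scores > 0))
    # keep the best window among overlapping qualifying ones
    picked: list[tuple[int, float, float]] = []
    for w in sorted(qualifying, key=lambda w: (-scores[w], w)):
        if all(abs(int(w) - p[0]) >= width for p in picked):
            picked.append((int(w), float(scores[w]), float(idents[w])))
    picked.sort(key=lambda t: t[0])
    return picked


def find_anchors(
    tracks: Sequence[TranslatedTrack],
    first_motif: MotifModel,
    last_motif: MotifModel,
    identity_threshold: float = 0.6,
) -> list[AnchorHit]:
    """Every presence-called occurrence of either anchor motif in any track."""
    anchors = []
    for t_idx, track in enumerate(tracks):
        for kind, motif in (("first", first_motif), ("last", last_motif)):
            for start, logodds, ident in _presence_windows(
                track.protein, motif, identity_threshold
            ):
                end = start + motif.width
                anchors.append(
                    AnchorHit(
                        track_index=t_idx,
                        kind=kind,
                        res_start=start,
                        res_end=end,
                        genomic=track.span_interval(start, end),
                        logodds=logodds,
                        consensus_identity=ident,
                    )
                )
    return anchors


def anchor_offsets_from_seeds(
    seed_proteins: Mapping[str, str],
    first_motif: MotifModel,
    last_motif: MotifModel,
    identity_threshold: float = 0.6,
) -> tuple[int, int]:
    """Mean N-terminal offset of the first anchor and mean C-terminal tail
    after the last anchor, over the seed proteins where both are present."""
    starts, tails = [], []
    for seq in seed_proteins.values():
        first_hit = scan_protein(seq, first_motif)
        last_hit = scan_protein(seq, last_motif)
        if call_presence(first_hit, identity_threshold):
            starts.append(first_hit.start - 1)
        if call_presence(last_hit, identity_threshold):
            tails.append(len(seq) - last_hit.end)
    if not starts or not tails:
        raise ValueError("anchors not present in any seed protein")
    return int(round(np.mean(starts))), int(round(np.mean(tails)))


@dataclass
class CandidateParalog:
    """A candidate clade member: genomic window, frame, protein, motif hits."""

    seq_id: str
    strand: str
    frame: int
    start: int  # forward-strand, 0-based half-open
    end: int
    protein: str
    hits: list[MotifHit] = field(default_factory=list)
    status: str = "unassigned"  # later: 'confirms-annotated' | 'novel'
    matched_gene: str | None = None

    @property
    def n_motifs_present(self) -> int:
        return len(self.hits)

    @property
    def length(self) -> int:
        return len(self.protein)


def _stop_free_segment(protein: str, res_start: int, res_end: int) -> tuple[int, int]:
    """The maximal stop-free residue run containing [res_start, res_end)."""
    lo = res_start
    while lo > 0 and protein[lo - 1] != "*":
        lo -= 1
    hi = res_end
    while hi < len(protein) and protein[hi] != "*":
        hi += 1
    return lo, hi


def build_candidates(
    anchors: Sequence[AnchorHit],
    tracks: Sequence[TranslatedTrack],
    target_len: int = 280,
    offsets: tuple[int, int] = (0, 0),
    min_length: int = 90,
    motifs: Sequence[MotifModel] | None = None,
    identity_threshold: float = 0.6,
) -> list[CandidateParalog]:
    """Turn anchor hits into candidate proteins.

    First/last anchors in the same track are paired when the spanned region
    is at most ``1.5 * target_len`` residues; a lone first anchor opens a
    window of ``target_len`` residues starting ``offsets[0]`` before it, and
    a lone last anchor a window ending ``offsets[1]`` after it.  Windows are
    clipped to the stop-free segment containing the anchor(s); candidates
    shorter than ``min_length`` are discarded.  When ``motifs`` are supplied
    each candidate is annotated with its present motif hits.
    """
    first_off, last_off = offsets
    by_track: dict[int, list[AnchorHit]] = {}
    for anchor in anchors:
        by_track.setdefault(anchor.track_index, []).append(anchor)

    # (track_index, res_start, res_end, anchor_residue)
    windows: list[tuple[int, int, int, int]] = []
    for t_idx, track_anchors in sorted(by_track.items()):
        firsts = sorted(
            (a for a in track_anchors if a.kind == "first"), key=lambda a: a.res_start
        )
        lasts = sorted(
            (a for a in track_anchors if a.kind == "last"), key=lambda a: a.res_start
        )
        used_lasts: set[int] = set()
        paired_firsts: set[int] = set()
        for fi, first in enumerate(firsts):
            for li, last in enumerate(lasts):
                if li in used_lasts:
                    continue
                if last.res_end <= first.res_start:
                    continue
                if last.res_end - first.res_start > 1.5 * target_len:
                    break
                used_lasts.add(li)
                paired_firsts.add(fi)
                windows.append(
                    (
                        t_idx,
                        first.res_start - first_off,
                        last.res_end + last_off,
                        first.res_start,
                    )
                )
                break
        for fi, first in enumerate(firsts):
            if fi not in paired_firsts:
                start = first.res_start - first_off
                windows.append((t_idx, start, start + target_len, first.res_start))
        for li, last in enumerate(lasts):
            if li not in used_lasts:
                end = last.res_end + last_off
                windows.append((t_idx, end - target_len, end, last.res_end - 1))

    # clip windows to the anchor's stop-free segment and build candidates
    candidates = []
    for t_idx, res_start, res_end, anchor_res in windows:
        track = tracks[t_idx]
        res_start = max(res_start, 0)
        res_end = min(res_end, len(track.protein))
        if res_end <= res_start:
            continue
        seg_lo, seg_hi = _stop_free_segment(track.protein, anchor_res, anchor_res + 1)
        seg_lo = max(seg_lo, res_start)
        seg_hi = min(seg_hi, res_end)
        if seg_hi <= seg_lo:
            continue
        protein = track.protein[seg_lo:seg_hi]
        if len(protein) < min_length:
            continue
        g_start, g_end = track.span_interval(seg_lo, seg_hi)
        cand = CandidateParalog(
            seq_id=track.seq_id,
            strand=track.strand,
            frame=track.frame,
            start=g_start,
            end=g_end,
            protein=protein,
        )
        if motifs is not None:
            arch = architecture(protein, motifs, identity_threshold=identity_threshold)
            cand.hits = arch.hits
        candidates.append(cand)
    return candidates


def filter_members(
    candidates: Sequence[CandidateParalog],
    motifs: Sequence[MotifModel],
    min_motifs: int = 3,
    identity_threshold: float = 0.6,
) -> list[CandidateParalog]:
    """Keep candidates with >= ``min_motifs`` present motifs; collapse overlaps.

    Candidates lacking hit annotations are scanned first.  Overlapping
    candidates on the same strand are collapsed to one (max motif count,
    then longer protein, then smaller start).
    """
    scored = []
    for cand in candidates:
        if not cand.hits:
            arch = architecture(
                cand.protein, motifs, identity_threshold=identity_threshold
            )
            cand.hits = arch.hits
        if cand.n_motifs_present >= min_motifs:
            scored.append(cand)
    scored.sort(key=lambda c: (-c.n_motifs_present, -c.length, c.start))
    kept: list[CandidateParalog] = []
    for cand in scored:
        overlaps = any(
            k.seq_id == cand.seq_id
            and k.strand == cand.strand
            and cand.start < k.end
            and k.start < cand.end
            for k in kept
        )
        if not overlaps:
            kept.append(cand)
    kept.sort(key=lambda c: (c.seq_id, c.start))
    return kept


def reconcile_with_annotation(
    members: Sequence[CandidateParalog],
    annotations: Sequence[GeneAnnotation],
    min_reciprocal_overlap: float = 0.5,
) -> list[CandidateParalog]:
    """Assign each member 'confirms-annotated' or 'novel' status.

    A member confirms an annotated gene when they share the strand and
    sequence and overlap by at least ``min_reciprocal_overlap`` of each
    feature's length (reciprocally).
    """
    for member in members:
        member.status = "novel"
        member.matched_gene = None
        for gene in annotations:
            if gene.seq_id != member.seq_id or gene.strand != member.strand:
                continue
            overlap = min(member.end, gene.end) - max(member.start, gene.start)
            if overlap <= 0:
                continue
            if (
                overlap >= min_reciprocal_overlap * (member.end - member.start)
                and overlap >= min_reciprocal_overlap * gene.length
            ):
                member.status = "confirms-annotated"
                member.matched_gene = gene.gene_id
                break
    return list(members)


def scan_genome(
    genome: Mapping[str, str],
    motifs: Sequence[MotifModel],
    seed_proteins: Mapping[str, str],
    annotations: Sequence[GeneAnnotation] = (),
    first_motif_id: str | None = None,
    last_motif_id: str | None = None,
    target_len: int = 280,
    min_motifs: int = 3,
    min_length: int = 90,
    identity_threshold: float = 0.6,
) -> list[CandidateParalog]:
    """Full pipeline: six-frame scan of every sequence, membership filter,
    annotation reconciliation.

    ``first_motif_id``/``last_motif_id`` designate the N-terminal-most and
    C-terminal-most anchor motifs in the seed architecture; by default they
    are inferred from the mean hit positions in the seed proteins.
    """
    by_id = {m.motif_id: m for m in motifs}
    if first_motif_id is None or last_motif_id is None:
        mean_start: dict[str, float] = {}
        for motif in motifs:
            starts = []
            for seq in seed_proteins.values():
                hit = scan_protein(seq, motif)
                if call_presence(hit, identity_threshold):
                    starts.append(hit.start)
            if starts:
                mean_start[motif.motif_id] = float(np.mean(starts))
        if not mean_start:
            raise ValueError("no motif is present in the seed proteins")
        inferred_first = min(mean_start, key=mean_start.get)
        inferred_last = max(mean_start, key=mean_start.get)
        first_motif_id = first_motif_id or inferred_first
        last_motif_id = last_motif_id or inferred_last
    first_motif = by_id[first_motif_id]
    last_motif = by_id[last_motif_id]
    offsets = anchor_offsets_from_seeds(
        seed_proteins, first_motif, last_motif, identity_threshold
    )

    members: list[CandidateParalog] = []
    for seq_id, seq in genome.items():
        tracks = six_frame_translate(seq, seq_id)
        anchors = find_anchors(tracks, first_motif, last_motif, identity_threshold)
        candidates = build_candidates(
            anchors,
            tracks,
            target_len=target_len,
            offsets=offsets,
            min_length=min_length,
            motifs=motifs,
            identity_threshold=identity_threshold,
        )
        members.extend(
            filter_members(candidates, motifs, min_motifs, identity_threshold)
        )
    return reconcile_with_annotation(members, annotations)
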