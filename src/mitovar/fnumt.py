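"""Detection of non-reference nuclear insertions of mtDNA (non-ref NUMTs).

An mtDNA segment inserted into the nuclear genome leaves two signals in a
short-read alignment against the insertion-free reference: junction reads
soft-clipped across the two insertion breakpoints (one part nuclear, one
part mitochondrial) and discordant pairs with one mate on each genome.
Junction reads are clustered by nuclear coordinate and mapping
orientation: start-side clusters (mitochondrial match preceded by the
clip, 'xxSxxM' on the mt contig) localise the start of the transferred
segment and the left nuclear breakpoint; end-side clusters ('xxMxxS')
localise its end and the right breakpoint.  Candidates supported by only
one orientation, or with conflicting orientations, are discarded — this
is what rejects chimeric-insertion false positives.

Because the mitochondrial genome is circular, segment coordinates use the
(start, end] convention: a segment spanning the artificial origin has a
start numerically larger than its end, and its size is never confused
with the complement arc.

Supporting mt-derived sequences are assembled into a consensus contig
(greedy overlap-layout-consensus) and realigned to the origin-unrolled
mitochondrial sequence to verify the segment and detect mismatch bases —
the candidate NUMT-derived false-positive variants (NUMT-FPs) that the
copy-number filters later remove from mtDNA callsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import edlib
import numpy as np
import pandas as pd

from .reference import (
    AlignedRead, CircularReference, circular_distance, circular_position,
    in_circular_segment, mt_segment_length, revcomp,
)

MIN_CLIP = 20
CLUSTER_WINDOW = 20
MIN_SUPPORT = 2
MIN_CLIP_IDENTITY = 0.90
MIN_CONTIG_IDENTITY = 0.90
ASSEMBLY_MIN_OVERLAP = 20
ASSEMBLY_MIN_IDENTITY = 0.95
HOM_THRESHOLD = 0.75
DISCORDANT_MAX_DISTANCE = 1000
SHARED_NUMT_TOLERANCE = 200     # bp; insertion sites within this are shared


@dataclass
class JunctionRead:
    """A soft-clipped read straddling one insertion breakpoint."""

    read_id: str
    nuclear_contig: str
    nuclear_bp: int               # breakpoint estimate on the nuclear genome
    mt_coord: int                 # segment start (side='start') or end
    side: str                     # 'start' or 'end'
    cigar_class: str              # 'SM' or 'MS' as seen on the mt contig
    mt_strand: str                # '+'/'-' of the mt-derived portion
    clip_seq: str
    mt_seq: str                   # mt-derived portion, mt-forward orientation


@dataclass
class NumtCall:
    mt_start: int
    mt_end: int
    segment_size: int
    nuclear_contig: str
    bp_left: int
    bp_right: int
    n_junction_start: int
    n_junction_end: int
    n_discordant: int = 0
    zygosity: str = ""
    zygosity_fraction: float = float("nan")
    contig_seq: str = ""
    assembled: bool = False
    mismatches: List[tuple] = field(default_factory=list)
    origin: str = ""
    junction_reads: List[JunctionRead] = field(default_factory=list)

    def contains_mt_position(self, pos: int, length: int = 16569) -> bool:
        return in_circular_segment(pos, self.mt_start, self.mt_end, length)


@dataclass(frozen=True)
class NumtFP:
    """A mismatch on an inserted segment: a candidate false mtDNA variant."""

    mt_pos: int
    ref: str
    obs: str
    parent_index: int = 0
    expected_vaf_threshold: float = float("nan")


# ---------------------------------------------------------------------------
# Junction extraction
# ---------------------------------------------------------------------------

def _best_infix(query: str, target: str):
    """Best edlib infix hit of query (either strand) in target."""
    fwd = edlib.align(query, target, mode="HW", task="locations")
    rev = edlib.align(revcomp(query), target, mode="HW", task="locations")
    if rev["editDistance"] < fwd["editDistance"]:
        return rev["editDistance"], rev["locations"][0], "-"
    return fwd["editDistance"], fwd["locations"][0], "+"


def extract_junction_reads(reads: Iterable[AlignedRead],
                           mt_ref: CircularReference,
                           nuclear_refs: Dict[str, CircularReference],
                           min_clip: int = MIN_CLIP,
                           min_identity: float = MIN_CLIP_IDENTITY
                           ) -> List[JunctionRead]:
    """Find reads whose soft-clipped portion maps to the other genome.

    A read fully mapped to one contig is never a junction read; clips
    shorter than ``min_clip`` or aligning below ``min_identity`` — or
    aligning better to the read's own genome (e.g. origin-spanning mt
    reads) — are excluded.
    """
    mt_doubled = mt_ref.doubled()
    L = mt_ref.length
    out: List[JunctionRead] = []
    for read in reads:
        if read.is_secondary or read.is_supplementary:
            continue
        clips = read.soft_clips()
        if len(clips) != 1 or clips[0][1] < min_clip:
            continue
        side_lr, clip_len, clip_seq = clips[0]
        on_mt = read.contig == mt_ref.name
        if on_mt:
            cross_targets = [(name, ref.sequence)
                             for name, ref in nuclear_refs.items()]
            own_dist, _, _ = _best_infix(clip_seq, mt_doubled)
        else:
            cross_targets = [("chrM", mt_doubled)]
            own = nuclear_refs.get(read.contig)
            own_dist, _, _ = _best_infix(clip_seq, own.sequence) \
                if own is not None else (len(clip_seq), None, "+")
        best = None
        for name, target in cross_targets:
            dist, loc, strand = _best_infix(clip_seq, target)
            if best is None or dist < best[0]:
                best = (dist, loc, strand, name)
        if best is None:
            continue
        dist, (loc_s, loc_e), strand, target_name = best
        if 1.0 - dist / clip_len < min_identity or dist >= own_dist:
            continue

        mapped_seq = read.seq[clip_len:] if side_lr == "L" \
            else read.seq[:len(read.seq) - clip_len]
        if on_mt:
            # clip is nuclear; mapped portion is the mt-derived sequence
            if side_lr == "L":      # xxSxxM: start side
                side = "start"
                cigar_class = "SM"
                mt_coord = circular_position(read.pos - 1, L)
                nuclear_bp = loc_e + 1          # clip ends at bp_left
            else:                   # xxMxxS: end side
                side = "end"
                cigar_class = "MS"
                mt_coord = circular_position(read.reference_end(), L)
                nuclear_bp = loc_s + 1          # clip starts at bp_right
            mt_seq = mapped_seq
            nuc_name = target_name
        else:
            # clip is mitochondrial
            if side_lr == "R":      # nuclear M..S crosses the left breakpoint
                side = "start"
                cigar_class = "SM"
                nuclear_bp = read.reference_end()
                mt_coord = circular_position((loc_s % L) + 1 - 1, L)
            else:                   # nuclear S..M crosses the right breakpoint
                side = "end"
                cigar_class = "MS"
                nuclear_bp = read.pos
                mt_coord = circular_position((loc_e % L) + 1, L)
            mt_seq = clip_seq if strand == "+" else revcomp(clip_seq)
            nuc_name = read.contig
        out.append(JunctionRead(
            read_id=read.qname, nuclear_contig=nuc_name,
            nuclear_bp=int(nuclear_bp), mt_coord=int(mt_coord), side=side,
            cigar_class=cigar_class, mt_strand=strand,
            clip_seq=clip_seq, mt_seq=mt_seq))
    return out


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _mode(values: Sequence[int]) -> int:
    """Most frequent value; ties resolved toward the smallest."""
    counts: Dict[int, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]


def cluster_junctions(junctions: Sequence[JunctionRead],
                      window: int = CLUSTER_WINDOW,
                      min_support: int = MIN_SUPPORT,
                      mt_length: int = 16569) -> List[NumtCall]:
    """Cluster junction reads into candidate NUMT calls.

    Single-linkage within ``window`` bp on the nuclear genome; candidates
    lacking either orientation class, or with strand-conflicting mt
    alignments, are discarded.
    """
    ordered = sorted(junctions, key=lambda j: (j.nuclear_contig,
                                               j.nuclear_bp))
    clusters: List[List[JunctionRead]] = []
    for j in ordered:
        if (clusters and clusters[-1][-1].nuclear_contig == j.nuclear_contig
                and j.nuclear_bp - clusters[-1][-1].nuclear_bp <= window):
            clusters[-1].append(j)
        else:
            clusters.append([j])
    out: List[NumtCall] = []
    for cluster in clusters:
        starts = [j for j in cluster if j.side == "start"]
        ends = [j for j in cluster if j.side == "end"]
        if len(starts) < min_support or len(ends) < min_support:
            continue
        if len({j.mt_strand for j in cluster}) > 1:
            continue              # orientation conflict
        mt_start = _mode([j.mt_coord for j in starts])
        mt_end = _mode([j.mt_coord for j in ends])
        bp_left = _mode([j.nuclear_bp for j in starts])
        bp_right = _mode([j.nuclear_bp for j in ends])
        if bp_left > bp_right:
            bp_left, bp_right = bp_right, bp_left
        out.append(NumtCall(
            mt_start=mt_start, mt_end=mt_end,
            segment_size=mt_segment_length(mt_start, mt_end, mt_length),
            nuclear_contig=cluster[0].nuclear_contig,
            bp_left=bp_left, bp_right=bp_right,
            n_junction_start=len(starts), n_junction_end=len(ends),
            junction_reads=list(cluster)))
    return out


# ---------------------------------------------------------------------------
# Discordant pairs and zygosity
# ---------------------------------------------------------------------------

def count_discordant_support(reads: Iterable[AlignedRead],
                             candidate: NumtCall,
                             mt_name: str = "chrM",
                             mt_length: int = 16569,
                             max_distance: int = DISCORDANT_MAX_DISTANCE,
                             pad: int = 150) -> int:
    """Pairs with one mate near the nuclear breakpoints, one on the segment."""
    seen = set()
    for read in reads:
        if read.is_secondary or read.is_supplementary:
            continue
        if read.contig != candidate.nuclear_contig:
            continue
        if read.mate_contig != mt_name or read.mate_pos is None:
            continue
        near = min(abs(read.pos - candidate.bp_left),
                   abs(read.pos - candidate.bp_right),
                   abs(read.reference_end() - candidate.bp_left),
                   abs(read.reference_end() - candidate.bp_right))
        if near > max_distance:
            continue
        mate_in = any(in_circular_segment(p, candidate.mt_start,
                                          candidate.mt_end, mt_length)
                      for p in (read.mate_pos, read.mate_pos + pad - 1))
        if mate_in:
            seen.add(read.qname)
    return len(seen)


def estimate_zygosity(candidate: NumtCall, supportive_reads: float,
                      mean_autosomal_coverage: float,
                      hom_threshold: float = HOM_THRESHOLD
                      ) -> Tuple[str, float]:
    """Zygosity from the fraction of supportive reads over mean coverage."""
    if mean_autosomal_coverage <= 0:
        raise ValueError("mean autosomal coverage must be positive")
    fraction = supportive_reads / mean_autosomal_coverage
    return ("hom" if fraction >= hom_threshold else "het"), float(fraction)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _overlap_len(a: str, b: str, min_overlap: int,
                 min_identity: float) -> int:
    """Longest suffix(a)/prefix(b) overlap passing the identity floor.

    Seeded with exact 16-mers taken at several offsets of ``b`` so that a
    sequencing error near the junction does not hide the overlap.
    """
    la, lb = len(a), len(b)
    best = 0
    tried = set()
    for off in range(0, min(40, lb - 16 + 1), 8):
        seed = b[off:off + 16]
        start = 0
        while True:
            p = a.find(seed, start)
            if p < 0:
                break
            start = p + 1
            shift = p - off
            if shift in tried or shift < 0:
                continue
            tried.add(shift)
            k = min(la - shift, lb)
            if k < min_overlap or k <= best:
                continue
            mism = sum(x != y for x, y in zip(a[shift:shift + k], b[:k]))
            if mism <= (1.0 - min_identity) * k:
                best = k
    return best


def _assemble_core(sequences: Sequence[str], min_overlap: int,
                   min_identity: float) -> Tuple[List[str], bool, int]:
    """Greedy longest-overlap-first merging; returns the final contigs
    (one per connected island), whether any merge happened, and the
    usable input count."""
    usable = [s for s in sequences if len(s) >= min_overlap]
    seqs = sorted(set(usable), key=len, reverse=True)
    if not seqs:
        return [], False, 0
    kept: List[str] = []
    for s in seqs:                       # drop contained sequences
        if not any(s in t for t in kept):
            kept.append(s)
    if len(kept) == 1:
        return kept, False, len(usable)

    items: Dict[int, str] = {i: s for i, s in enumerate(kept)}
    overlaps: Dict[tuple, int] = {}
    for i in items:
        for j in items:
            if i != j:
                k = _overlap_len(items[i], items[j], min_overlap,
                                 min_identity)
                if k:
                    overlaps[(i, j)] = k
    next_id = len(items)
    merged_any = False
    while overlaps:
        (i, j), k = max(overlaps.items(), key=lambda kv: (kv[1], -kv[0][0]))
        merged = items[i] + items[j][k:]
        for key in [key for key in overlaps if i in key or j in key]:
            del overlaps[key]
        del items[i], items[j]
        drop = [m for m, s in items.items() if s in merged]
        for m in drop:
            for key in [key for key in overlaps if m in key]:
                del overlaps[key]
            del items[m]
        items[next_id] = merged
        for m in items:
            if m != next_id:
                k1 = _overlap_len(merged, items[m], min_overlap, min_identity)
                if k1:
                    overlaps[(next_id, m)] = k1
                k2 = _overlap_len(items[m], merged, min_overlap, min_identity)
                if k2:
                    overlaps[(m, next_id)] = k2
        next_id += 1
        merged_any = True
    contigs = sorted(items.values(), key=len, reverse=True)
    return contigs, merged_any, len(usable)


def assemble_numt_contig(sequences: Sequence[str],
                         min_overlap: int = ASSEMBLY_MIN_OVERLAP,
                         min_identity: float = ASSEMBLY_MIN_IDENTITY
                         ) -> Tuple[str, bool]:
    """Greedy overlap-layout-consensus assembly of mt-derived sequences.

    Merges the pair with the longest passing overlap first; a final
    majority vote over the inputs polishes the consensus.  Returns
    ``(contig, assembled)``; with no overlap structure the longest input
    is returned flagged unassembled.
    """
    contigs, merged_any, n_usable = _assemble_core(sequences, min_overlap,
                                                   min_identity)
    if not contigs:
        return "", False
    if len(contigs) == 1 and not merged_any:
        return contigs[0], n_usable > 1
    contig = _polish(contigs[0], list(sequences))
    return contig, merged_any and len(contigs) == 1


def assemble_numt_islands(sequences: Sequence[str],
                          min_overlap: int = ASSEMBLY_MIN_OVERLAP,
                          min_identity: float = ASSEMBLY_MIN_IDENTITY
                          ) -> List[str]:
    """All assembled islands (longest first), each majority-polished.

    A segment longer than the fragment span may not assemble into one
    contig; mismatch detection then proceeds per island.
    """
    contigs, _, _ = _assemble_core(sequences, min_overlap, min_identity)
    return [_polish(c, list(sequences)) for c in contigs]


def _polish(contig: str, sequences: Sequence[str]) -> str:
    """Majority vote per column from reads placed by exact 16-mer seeds."""
    if len(contig) < 16:
        return contig
    votes = [dict() for _ in range(len(contig))]
    for s in sequences:
        placed = None
        for off in range(0, max(1, len(s) - 16), 24):
            p = contig.find(s[off:off + 16])
            if p >= 0:
                placed = p - off
                break
        if placed is None:
            continue
        for qi, ch in enumerate(s):
            ci = placed + qi
            if 0 <= ci < len(contig):
                votes[ci][ch] = votes[ci].get(ch, 0) + 1
    out = []
    for i, tally in enumerate(votes):
        if tally:
            out.append(sorted(tally.items(),
                              key=lambda kv: (-kv[1], kv[0]))[0][0])
        else:
            out.append(contig[i])
    return "".join(out)


# ---------------------------------------------------------------------------
# Contig verification against the mitochondrial reference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContigPlacement:
    mt_first: int                 # first aligned mt base (1-based)
    mt_last: int                  # last aligned mt base
    strand: str
    identity: float
    mismatches: Tuple[tuple, ...]
    n_indels: int


def align_contig_to_mt(contig: str, mt_ref: CircularReference,
                       min_identity: float = MIN_CONTIG_IDENTITY
                       ) -> Optional[ContigPlacement]:
    """Gapped infix alignment of a contig to the origin-unrolled genome.

    Returns the placement plus every mismatched base as an (mt position,
    reference base, observed base) record, or ``None`` below the identity
    floor.
    """
    if not contig:
        return None
    target = mt_ref.doubled()
    L = mt_ref.length
    best = None
    for strand, query in (("+", contig), ("-", revcomp(contig))):
        res = edlib.align(query, target, mode="HW", task="path")
        if best is None or res["editDistance"] < best[0]["editDistance"]:
            best = (res, strand, query)
    res, strand, query = best
    identity = 1.0 - res["editDistance"] / max(1, len(contig))
    if identity < min_identity:
        return None
    loc_s, loc_e = res["locations"][0]
    nice = edlib.getNiceAlignment(res, query, target)
    q_al = nice["query_aligned"]
    t_al = nice["target_aligned"]
    mismatches = []
    n_indels = 0
    t_idx = loc_s
    for qc, tc in zip(q_al, t_al):
        if qc == "-" or tc == "-":
            n_indels += 1
            if tc != "-":
                t_idx += 1
            continue
        if qc != tc:
            mismatches.append((circular_position(t_idx + 1, L), tc, qc))
        t_idx += 1
    return ContigPlacement(
        mt_first=circular_position(loc_s + 1, L),
        mt_last=circular_position(loc_e + 1, L),
        strand=strand, identity=identity,
        mismatches=tuple(mismatches), n_indels=n_indels)


# ---------------------------------------------------------------------------
# Origin classification and evaluation metrics
# ---------------------------------------------------------------------------

def classify_origin(tumor_calls: Sequence[NumtCall],
                    normal_calls: Sequence[NumtCall],
                    tolerance: int = SHARED_NUMT_TOLERANCE) -> List[tuple]:
    """Match NUMTs across a tumor/normal pair and label their origin.

    Insertions whose nuclear positions lie within ``tolerance`` bp are the
    same event: shared -> germline, tumor-only -> somatic, normal-only ->
    loss.  Labels are also written onto the calls.
    """
    used = set()
    out = []
    for t in tumor_calls:
        match = None
        for i, n in enumerate(normal_calls):
            if i in used or n.nuclear_contig != t.nuclear_contig:
                continue
            if abs(n.bp_left - t.bp_left) <= tolerance:
                match = i
                break
        if match is not None:
            used.add(match)
            t.origin = normal_calls[match].origin = "germline"
            out.append(("germline", t, normal_calls[match]))
        else:
            t.origin = "somatic"
            out.append(("somatic", t, None))
    for i, n in enumerate(normal_calls):
        if i not in used:
            n.origin = "loss"
            out.append(("loss", None, n))
    return out


def breakpoint_distance(call: NumtCall, truth,
                        mt_length: int = 16569) -> List[int]:
    """Absolute breakpoint errors against a matched truth record.

    Three distances (mt start, mt end — both on the circular metric — and
    the nuclear site), or four when the call reports two distinct nuclear
    positions.
    """
    if call is None or truth is None:
        raise ValueError("breakpoint_distance requires a matched pair")
    dists = [circular_distance(call.mt_start, truth.mt_start, mt_length),
             circular_distance(call.mt_end, truth.mt_end, mt_length),
             abs(call.bp_left - truth.bp_left)]
    if call.bp_left != call.bp_right:
        dists.append(abs(call.bp_right - truth.bp_right))
    return dists


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def call_numts(reads: Sequence[AlignedRead], mt_ref: CircularReference,
               nuclear_refs: Dict[str, CircularReference],
               mean_autosomal_coverage: float, *,
               min_clip: int = MIN_CLIP,
               window: int = CLUSTER_WINDOW,
               min_support: int = MIN_SUPPORT,
               min_identity: float = MIN_CLIP_IDENTITY,
               read_len: int = 150,
               verify_pad: int = 30
               ) -> Tuple[List[NumtCall], List[NumtFP]]:
    """End-to-end NUMT detection on one sample's alignment records."""
    reads = list(reads)
    junctions = extract_junction_reads(reads, mt_ref, nuclear_refs,
                                       min_clip, min_identity)
    candidates = cluster_junctions(junctions, window, min_support,
                                   mt_ref.length)
    calls: List[NumtCall] = []
    fps: List[NumtFP] = []
    for cand in candidates:
        cand.n_discordant = count_discordant_support(
            reads, cand, mt_ref.name, mt_ref.length, pad=read_len)
        # junction capture needs min_clip anchored on both sides of the
        # breakpoint, so scale the per-side mean back to full coverage
        per_side = (cand.n_junction_start + cand.n_junction_end) / 2.0
        capture = max(1e-9, (read_len - 2 * min_clip) / read_len)
        cand.zygosity, cand.zygosity_fraction = estimate_zygosity(
            cand, per_side / capture, mean_autosomal_coverage)

        seqs = [j.mt_seq for j in cand.junction_reads]
        junction_ids = {j.read_id for j in cand.junction_reads}
        mt_doubled = mt_ref.doubled()
        nuc_seq = nuclear_refs[cand.nuclear_contig].sequence \
            if cand.nuclear_contig in nuclear_refs else ""
        for read in reads:
            if read.contig != mt_ref.name:
                continue
            discordant_mate = (
                read.mate_contig == cand.nuclear_contig
                and read.mate_pos is not None
                and min(abs(read.mate_pos - cand.bp_left),
                        abs(read.mate_pos - cand.bp_right))
                <= DISCORDANT_MAX_DISTANCE)
            # reads mapped within the candidate segment also feed the
            # assembly, covering the segment interior
            on_segment = any(
                in_circular_segment(p, cand.mt_start, cand.mt_end,
                                    mt_ref.length)
                for p in (read.pos, read.reference_end()))
            if ((discordant_mate or on_segment)
                    and not (read.qname in junction_ids
                             and "S" in read.cigar)):
                # mt-derived mates; reads clipped at the circular origin
                # still belong to the segment, but any clip that aligns
                # better to the nuclear genome is trimmed first
                seq = read.seq
                for side, length, clip in read.soft_clips():
                    trim = length < 10
                    if not trim and nuc_seq:
                        mt_d, _, _ = _best_infix(clip, mt_doubled)
                        nuc_d, _, _ = _best_infix(clip, nuc_seq)
                        trim = nuc_d <= mt_d
                    if trim:
                        seq = seq[length:] if side == "L" else seq[:-length]
                if len(seq) >= ASSEMBLY_MIN_OVERLAP:
                    seqs.append(seq)
        islands = assemble_numt_islands(seqs)
        pad = verify_pad
        padded_start = circular_position(cand.mt_start - pad, mt_ref.length)
        padded_end = circular_position(cand.mt_end + pad, mt_ref.length)
        placed = []
        covered = 0
        for contig in islands:
            placement = align_contig_to_mt(contig, mt_ref)
            if placement is None or placement.strand != "+":
                continue          # contradicts an mtDNA origin
            inside = all(in_circular_segment(p, padded_start, padded_end,
                                             mt_ref.length)
                         for p in (placement.mt_first, placement.mt_last))
            if not inside:
                continue          # contradicts the junction-derived segment
            placed.append((contig, placement))
            covered += mt_segment_length(
                circular_position(placement.mt_first - 1, mt_ref.length),
                placement.mt_last, mt_ref.length)
        if not placed:
            continue              # no island confirms the segment
        cand.contig_seq = placed[0][0]
        cand.assembled = len(placed) == 1 and \
            covered >= cand.segment_size - 2 * pad
        seen_mism = set()
        for _, placement in placed:
            for mt_pos, ref_base, obs_base in placement.mismatches:
                if cand.contains_mt_position(mt_pos, mt_ref.length) \
                        and (mt_pos, obs_base) not in seen_mism:
                    seen_mism.add((mt_pos, obs_base))
                    cand.mismatches.append((mt_pos, ref_base, obs_base))
                    fps.append(NumtFP(mt_pos, ref_base, obs_base,
                                      parent_index=len(calls)))
        calls.append(cand)
    return calls, fps


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["mt_start", "mt_end", "segment_size", "nuclear_chrom",
                "bp_left", "bp_right", "junction_fwd", "junction_rev",
                "discordant", "zygosity", "zygosity_fraction", "origin",
                "assembled", "contig_id"]


def write_numt_calls(calls: Sequence[NumtCall], path: str) -> None:
    rows = []
    for i, c in enumerate(calls):
        rows.append({
            "mt_start": c.mt_start, "mt_end": c.mt_end,
            "segment_size": c.segment_size,
            "nuclear_chrom": c.nuclear_contig,
            "bp_left": c.bp_left, "bp_right": c.bp_right,
            "junction_fwd": c.n_junction_start,
            "junction_rev": c.n_junction_end,
            "discordant": c.n_discordant,
            "zygosity": c.zygosity,
            "zygosity_fraction": round(c.zygosity_fraction, 4),
            "origin": c.origin or ".",
            "assembled": c.assembled,
            "contig_id": f"numt_{i}",
        })
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t",
                                                    index=False)


def read_numt_calls(path: str) -> List[NumtCall]:
    df = pd.read_csv(path, sep="\t")
    calls = []
    for _, row in df.iterrows():
        calls.append(NumtCall(
            mt_start=int(row.mt_start), mt_end=int(row.mt_end),
            segment_size=int(row.segment_size),
            nuclear_contig=str(row.nuclear_chrom),
            bp_left=int(row.bp_left), bp_right=int(row.bp_right),
            n_junction_start=int(row.junction_fwd),
            n_junction_end=int(row.junction_rev),
            n_discordant=int(row.discordant),
            zygosity=str(row.zygosity),
            zygosity_fraction=float(row.zygosity_fraction),
            origin="" if str(row.origin) == "." else str(row.origin),
            assembled=bool(row.assembled)))
    return calls


def write_numt_fps(fps: Sequence[NumtFP], path: str) -> None:
    pd.DataFrame(
        [{"mt_pos": f.mt_pos, "ref": f.ref, "obs": f.obs,
          "parent_index": f.parent_index,
          "expected_vaf_threshold": f.expected_vaf_threshold}
         for f in fps],
        columns=["mt_pos", "ref", "obs", "parent_index",
                 "expected_vaf_threshold"]).to_csv(path, sep="\t",
                                                   index=False)
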