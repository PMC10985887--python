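"""Synthetic read-set generator with ground-truth ledgers.

Emulates the evaluation design used for the callers: a fixed panel of 20
SNVs, 5 short insertions and 5 short deletions planted on the circular
mitochondrial reference outside the artifact blacklist, sequenced as
paired-end reads at a grid of heteroplasmy fractions (VAF 0.001-0.5) and
mean depths (5,000-20,000x).  The mutated template is sequenced at
``vaf x depth`` and the wild-type template at the remainder, so e.g. VAF
0.001 at 5,000x gives the mutated molecule 5x coverage.

Reads are emitted as already-placed alignment records (true origins are
known, so coordinates and CIGARs are exact) with base-quality-consistent
substitution errors drawn from a configurable Phred profile; no external
aligner is required.  A separate generator plants mtDNA segments into a
nuclear contig and emits the junction (soft-clipped) and discordant read
pairs such an insertion produces, including segments spanning the
circular origin.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import pearsonr

from .reference import (
    DEL, INS, SNV, AlignedRead, Blacklist, CircularReference, ReadBlock,
    circular_position, decode_seq, encode_seq, mt_segment_length,
)

PAPER_VAFS = (0.001, 0.005, 0.01, 0.05, 0.1, 0.25, 0.5)
PAPER_DEPTHS = (5000, 10000, 20000)


@dataclass(frozen=True)
class QualityModel:
    """Phred quality profile for simulated bases (default mean Q30)."""

    mean: float = 30.0
    sd: float = 3.0
    qmin: int = 13
    qmax: int = 40

    def draw(self, rng: np.random.Generator, shape) -> np.ndarray:
        q = np.round(rng.normal(self.mean, self.sd, size=shape))
        return np.clip(q, self.qmin, self.qmax).astype(np.uint8)


@dataclass(frozen=True)
class VariantSimConfig:
    n_snv: int = 20
    n_ins: int = 5
    n_del: int = 5
    vaf: float = 0.01
    depth: float = 10_000.0
    read_len: int = 150
    frag_mean: float = 400.0
    frag_sd: float = 60.0
    indel_min: int = 1
    indel_max: int = 5
    min_spacing: int = 12
    quality: QualityModel = QualityModel()
    blacklist: Blacklist = field(default_factory=Blacklist.default_mt)

    @property
    def n_variants(self) -> int:
        return self.n_snv + self.n_ins + self.n_del


@dataclass(frozen=True)
class PlantedVariant:
    pos: int
    ref: str
    alt: str
    vtype: str
    vaf: float

    def key(self):
        return (self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class NumtTruth:
    """Planted nuclear insertion of an mtDNA segment, circular-aware."""

    mt_start: int                 # (start, end] convention
    mt_end: int
    segment_size: int
    nuclear_name: str
    bp_left: int                  # last reference base before the insertion
    bp_right: int                 # first reference base after it
    zygosity: str
    mismatches: Tuple[tuple, ...] = ()


@dataclass
class TruthLedger:
    """Everything needed to score a callset without re-simulation."""

    variants: List[PlantedVariant] = field(default_factory=list)
    numts: List[NumtTruth] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"variants": [asdict(v) for v in self.variants],
                       "numts": [asdict(n) for n in self.numts]}, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "TruthLedger":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            variants=[PlantedVariant(**v) for v in raw.get("variants", [])],
            numts=[NumtTruth(**{**n, "mismatches":
                                tuple(tuple(m) for m in n["mismatches"])})
                   for n in raw.get("numts", [])])


# ---------------------------------------------------------------------------
# Variant planting
# ---------------------------------------------------------------------------

@dataclass
class MutatedTemplate:
    """Mutated copy of the reference plus the template->reference map.

    ``pieces`` is an ordered list of (template_start, kind, length,
    ref_start) runs, kind 'M' (match, 0-based ref_start) or 'I'
    (insertion, ref_start = anchor).  Deletions appear as gaps between
    consecutive 'M' pieces.
    """

    codes: np.ndarray
    pieces: List[tuple]

    @property
    def length(self) -> int:
        return len(self.codes)

    def piece_starts(self) -> List[int]:
        return [p[0] for p in self.pieces]


def _materialise(reference: CircularReference,
                 rng: np.random.Generator) -> np.ndarray:
    """Wild-type template: reference with placeholder 'N's given a base."""
    codes = reference.codes.copy()
    n_pos = np.nonzero(codes == 4)[0]
    if len(n_pos):
        codes[n_pos] = rng.integers(0, 4, size=len(n_pos), dtype=np.uint8)
    return codes


def plant_variants(reference: CircularReference, config: VariantSimConfig,
                   rng: Optional[np.random.Generator] = None,
                   seed: Optional[int] = None
                   ) -> Tuple[MutatedTemplate, np.ndarray, TruthLedger]:
    """Plant the variant panel; returns (mutated, wild_codes, ledger).

    Positions are uniform over the genome excluding the blacklist and
    placeholder bases, with a minimum spacing so events never overlap.
    Deterministic under a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    L = reference.length
    wild = _materialise(reference, rng)
    bad = np.zeros(L + 1, dtype=bool)
    for p in config.blacklist.positions():
        if p <= L:
            bad[p] = True
    bad[0] = True
    if reference.codes is not None:
        bad[1:][reference.codes == 4] = True

    types = ([SNV] * config.n_snv + [INS] * config.n_ins
             + [DEL] * config.n_del)
    rng.shuffle(types)
    candidates = rng.permutation(np.arange(2, L - config.indel_max - 1))
    chosen: List[Tuple[int, str]] = []
    taken: List[int] = []
    span = config.min_spacing + config.indel_max
    ci = 0
    for vtype in types:
        placed = False
        while ci < len(candidates):
            pos = int(candidates[ci])
            ci += 1
            if bad[pos]:
                continue
            if vtype == DEL and bad[pos + 1:pos + config.indel_max + 1].any():
                continue
            if any(abs(pos - t) <= span for t in taken):
                continue
            chosen.append((pos, vtype))
            taken.append(pos)
            placed = True
            break
        if not placed:
            raise ValueError("not enough placeable positions for the panel")

    chosen.sort()
    variants: List[PlantedVariant] = []
    mut = wild.copy()
    indel_events: List[tuple] = []    # (anchor pos 1-based, kind, payload)
    for pos, vtype in chosen:
        anchor_code = int(wild[pos - 1])
        anchor_base = "ACGT"[anchor_code]
        if vtype == SNV:
            alt_code = int((anchor_code + rng.integers(1, 4)) % 4)
            mut[pos - 1] = alt_code
            variants.append(PlantedVariant(pos, anchor_base,
                                           "ACGT"[alt_code], SNV, config.vaf))
        elif vtype == INS:
            n = int(rng.integers(config.indel_min, config.indel_max + 1))
            ins = decode_seq(rng.integers(0, 4, size=n, dtype=np.uint8))
            indel_events.append((pos, INS, ins))
            variants.append(PlantedVariant(pos, anchor_base,
                                           anchor_base + ins, INS, config.vaf))
        else:
            n = int(rng.integers(config.indel_min, config.indel_max + 1))
            deleted = decode_seq(wild[pos:pos + n])
            indel_events.append((pos, DEL, n))
            variants.append(PlantedVariant(pos, anchor_base + deleted,
                                           anchor_base, DEL, config.vaf))

    # assemble the mutated template and its piece map
    segments: List[np.ndarray] = []
    pieces: List[tuple] = []
    tpl = 0
    ref_cursor = 0                     # 0-based
    for pos, kind, payload in indel_events:
        run = pos - ref_cursor         # copy through the anchor base
        segments.append(mut[ref_cursor:pos])
        pieces.append((tpl, "M", run, ref_cursor))
        tpl += run
        ref_cursor = pos
        if kind == INS:
            ins_codes = encode_seq(payload)
            segments.append(ins_codes)
            pieces.append((tpl, "I", len(ins_codes), pos))
            tpl += len(ins_codes)
        else:
            ref_cursor += int(payload)
    segments.append(mut[ref_cursor:])
    pieces.append((tpl, "M", L - ref_cursor, ref_cursor))
    template = MutatedTemplate(np.concatenate(segments), pieces)
    return template, wild, TruthLedger(variants=list(variants))


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _read_placement(pieces, starts, t0: int, rl: int):
    """Reference position and CIGAR for a template-coordinate read."""
    i = bisect_right(starts, t0) - 1
    remaining = rl
    cur = t0
    ops: List[tuple] = []
    ref_pos = None
    last_ref_end = None
    while remaining > 0:
        tpl_start, kind, plen, ref_start = pieces[i]
        off = cur - tpl_start
        take = min(remaining, plen - off)
        if kind == "M":
            if ref_pos is None:
                ref_pos = ref_start + off
            elif last_ref_end is not None and ref_start > last_ref_end:
                ops.append(("D", ref_start - last_ref_end))
            ops.append(("M", take))
            last_ref_end = ref_start + off + take
        else:
            ops.append(("I", take))
        cur += take
        remaining -= take
        if off + take == plen:
            i += 1
    # leading/trailing insertions become soft clips
    if ops and ops[0][0] == "I":
        ops[0] = ("S", ops[0][1])
    if ops and ops[-1][0] == "I":
        ops[-1] = ("S", ops[-1][1])
    merged: List[list] = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1][1] += n
        else:
            merged.append([op, n])
    cigar = "".join(f"{n}{op}" for op, n in merged)
    return ref_pos, cigar


def simulate_reads(mutated: MutatedTemplate, wild: np.ndarray,
                   config: VariantSimConfig,
                   rng: Optional[np.random.Generator] = None,
                   seed: Optional[int] = None,
                   contig: str = "chrM") -> ReadBlock:
    """Draw paired 150-bp reads from the mutated and wild templates.

    The mutated template is sampled at ``vaf x depth`` and the wild-type
    at ``(1 - vaf) x depth``; alignments are emitted directly from the
    known read origins.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rl = config.read_len
    L = len(wild)
    per_frag = 2 * rl
    n_total = int(round(config.depth * L / per_frag))
    n_mut = int(round(config.vaf * config.depth * L / per_frag))
    n_wild = n_total - n_mut
    if config.vaf > 0 and config.vaf * config.depth < 1:
        import warnings
        warnings.warn("expected mutated coverage below 1x", stacklevel=2)

    wild_pieces = [(0, "M", L, 0)]
    specs = [(wild, wild_pieces, n_wild, 0),
             (mutated.codes, mutated.pieces, n_mut, 1)]

    all_pos, all_strand, all_seq, all_qual = [], [], [], []
    all_cigid, all_frag, all_origin = [], [], []
    cigars = [f"{rl}M"]
    cigar_index = {cigars[0]: 0}
    frag_base = 0
    for codes, pieces, n_frag, origin in specs:
        if n_frag <= 0:
            frag_base += max(0, n_frag)
            continue
        T = len(codes)
        flen = np.clip(np.round(rng.normal(config.frag_mean, config.frag_sd,
                                           n_frag)),
                       rl, min(2 * config.frag_mean, T)).astype(np.int64)
        start = (rng.random(n_frag) * (T - flen + 1)).astype(np.int64)
        t1 = start                       # forward mate
        t2 = start + flen - rl           # reverse mate
        starts_list = [s for s, *_ in pieces]
        for t0, strand in ((t1, 0), (t2, 1)):
            offs = np.arange(rl)
            seq = np.empty((n_frag, rl), dtype=np.uint8)
            qual = np.empty((n_frag, rl), dtype=np.uint8)
            for lo in range(0, n_frag, 100_000):
                sl = slice(lo, min(lo + 100_000, n_frag))
                seq[sl] = codes[t0[sl, None] + offs[None, :]]
                qual[sl] = config.quality.draw(rng, seq[sl].shape)
                err = rng.random(seq[sl].shape) < np.power(
                    10.0, -(qual[sl] / 10.0))
                shift = rng.integers(1, 4, size=int(err.sum()),
                                     dtype=np.uint8)
                seq[sl][err] = (seq[sl][err] + shift) % 4

            if len(pieces) == 1:
                ref_pos = t0.copy()
                cig = np.zeros(n_frag, dtype=np.int32)
            else:
                boundaries = np.array(starts_list[1:], dtype=np.int64)
                lo = np.searchsorted(boundaries, t0, side="right")
                hi = np.searchsorted(boundaries, t0 + rl - 1, side="right")
                piece_kind_m = np.array([p[1] == "M" for p in pieces])
                easy = (lo == hi) & piece_kind_m[lo]
                ref_pos = np.empty(n_frag, dtype=np.int64)
                cig = np.zeros(n_frag, dtype=np.int32)
                ref_off = np.array([p[3] - p[0] if p[1] == "M" else 0
                                    for p in pieces], dtype=np.int64)
                ref_pos[easy] = t0[easy] + ref_off[lo[easy]]
                for j in np.nonzero(~easy)[0]:
                    rp, cigar = _read_placement(pieces, starts_list,
                                                int(t0[j]), rl)
                    ref_pos[j] = rp if rp is not None else 0
                    if cigar not in cigar_index:
                        cigar_index[cigar] = len(cigars)
                        cigars.append(cigar)
                    cig[j] = cigar_index[cigar]
            all_pos.append(ref_pos)
            all_strand.append(np.full(n_frag, strand, dtype=np.uint8))
            all_seq.append(seq)
            all_qual.append(qual)
            all_cigid.append(cig)
            all_frag.append(frag_base + np.arange(n_frag, dtype=np.int64))
            all_origin.append(np.full(n_frag, origin, dtype=np.uint8))
        frag_base += n_frag

    return ReadBlock(
        contig=contig, read_len=rl,
        pos=np.concatenate(all_pos),
        strand=np.concatenate(all_strand),
        mapq=np.full(sum(len(p) for p in all_pos), 60, dtype=np.uint8),
        seq=np.vstack(all_seq),
        qual=np.vstack(all_qual),
        cigar_id=np.concatenate(all_cigid),
        cigars=cigars,
        frag_id=np.concatenate(all_frag),
        origin=np.concatenate(all_origin),
    )


def simulate_dataset(reference: CircularReference, config: VariantSimConfig,
                     seed: int) -> Tuple[ReadBlock, TruthLedger]:
    """Plant the panel and sequence it in one deterministic step."""
    rng = np.random.default_rng(seed)
    template, wild, ledger = plant_variants(reference, config, rng)
    block = simulate_reads(template, wild, config, rng,
                           contig=reference.name)
    return block, ledger


def write_fastq(block: ReadBlock, prefix: str) -> Tuple[str, str]:
    """Paired FASTQ files (mate 1 = forward reads, mate 2 = reverse)."""
    paths = (f"{prefix}_R1.fastq", f"{prefix}_R2.fastq")
    handles = [open(p, "w") for p in paths]
    try:
        for i in range(block.n_reads):
            mate = int(block.strand[i])
            seq = decode_seq(block.seq[i])
            qual = "".join(chr(q + 33) for q in block.qual[i])
            handles[mate].write(
                f"@frag{block.frag_id[i]}/{mate + 1}\n{seq}\n+\n{qual}\n")
    finally:
        for fh in handles:
            fh.close()
    return paths


# ---------------------------------------------------------------------------
# NUMT planting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NumtSimConfig:
    mt_start: int = 16089         # (start, end]: may wrap the origin
    mt_end: int = 61
    nuclear_len: int = 12_000
    insert_pos: Optional[int] = None     # bp_left; default = contig middle
    zygosity: str = "het"
    n_mismatches: int = 0
    depth: float = 30.0
    read_len: int = 150
    frag_mean: float = 400.0
    frag_sd: float = 60.0
    error_rate: float = 0.0
    base_quality: int = 37
    window: int = 2000
    mismatch_margin: int = 30


def plant_numt(mt_ref: CircularReference, config: NumtSimConfig,
               rng: Optional[np.random.Generator] = None,
               seed: Optional[int] = None,
               nuclear_ref: Optional[CircularReference] = None
               ) -> Tuple[List[AlignedRead], CircularReference, NumtTruth]:
    """Plant an mtDNA segment into a nuclear contig and sequence the locus.

    Emits the alignment records the insertion produces against the
    *reference* (which lacks the insertion): reads crossing a breakpoint
    are soft-clipped, reads inside the segment map to the mitochondrial
    contig, and cross-genome pairs become discordant.  Segments may span
    the circular origin (``mt_start > mt_end``).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if nuclear_ref is None:
        nuclear_ref = CircularReference.random_nuclear(
            int(rng.integers(0, 2**31 - 1)), config.nuclear_len, "chr1")
    size = mt_segment_length(config.mt_start, config.mt_end, mt_ref.length)
    if size >= mt_ref.length:
        raise ValueError("segment as long as the whole mitochondrial genome")
    insert = encode_seq(mt_ref.segment(config.mt_start, config.mt_end))
    insert[insert == 4] = 0       # placeholder base materialised as 'A'

    margin = min(config.mismatch_margin, max(0, size // 2 - 1))
    mism_offsets = []
    if config.n_mismatches > 0:
        lo, hi = margin, size - margin
        mism_offsets = sorted(
            rng.choice(np.arange(lo, hi), size=config.n_mismatches,
                       replace=False).tolist())
    mismatches = []
    for off in mism_offsets:
        ref_code = int(insert[off])
        alt_code = int((ref_code + rng.integers(1, 4)) % 4)
        insert[off] = alt_code
        mt_pos = circular_position(config.mt_start + 1 + off, mt_ref.length)
        mismatches.append((mt_pos, "ACGT"[ref_code], "ACGT"[alt_code]))

    P = config.insert_pos or nuclear_ref.length // 2
    nuc = nuclear_ref.codes
    hap = np.concatenate([nuc[:P], insert, nuc[P:]])
    truth = NumtTruth(
        mt_start=config.mt_start, mt_end=config.mt_end, segment_size=size,
        nuclear_name=nuclear_ref.name, bp_left=P, bp_right=P + 1,
        zygosity=config.zygosity, mismatches=tuple(mismatches))

    rl = config.read_len
    span = 2 * config.window + size
    n_frag = int(round(config.depth * span / (2 * rl)))
    reads: List[AlignedRead] = []
    for fi in range(n_frag):
        from_hap = config.zygosity == "hom" or rng.random() < 0.5
        flen = int(np.clip(round(rng.normal(config.frag_mean,
                                            config.frag_sd)), rl, 2000))
        if from_hap:
            lo = max(0, P - config.window - flen)
            hi = min(len(hap) - flen, P + size + config.window)
        else:
            lo = max(0, P - config.window - flen)
            hi = min(len(nuc) - flen, P + config.window)
        start = int(rng.integers(lo, hi + 1))
        source = hap if from_hap else nuc
        mates = []
        for mate_i, (t0, is_rev) in enumerate(((start, False),
                                               (start + flen - rl, True))):
            seq = source[t0:t0 + rl].copy()
            if config.error_rate > 0:
                err = rng.random(rl) < config.error_rate
                shift = rng.integers(1, 4, size=int(err.sum()),
                                     dtype=np.uint8)
                seq[err] = (seq[err] + shift) % 4
            if from_hap:
                contig, pos, cigar = _place_hap_read(
                    t0, rl, P, size, config.mt_start, mt_ref.length,
                    nuclear_ref.name)
            else:
                contig, pos, cigar = nuclear_ref.name, t0 + 1, f"{rl}M"
            mates.append((contig, pos, cigar, seq, is_rev))
        (c1, p1, g1, s1, r1), (c2, p2, g2, s2, r2) = mates
        proper = c1 == c2
        for (contig, pos, cigar, seq, is_rev), (mc, mp) in (
                ((c1, p1, g1, s1, r1), (c2, p2)),
                ((c2, p2, g2, s2, r2), (c1, p1))):
            reads.append(AlignedRead(
                qname=f"numt_frag{fi}", contig=contig, pos=pos,
                mapq=60, cigar=cigar, seq=decode_seq(seq),
                qual=np.full(rl, config.base_quality, dtype=np.uint8),
                is_reverse=is_rev, is_proper_pair=proper,
                mate_contig=mc, mate_pos=mp))
    return reads, nuclear_ref, truth


def _place_hap_read(t0: int, rl: int, P: int, size: int, mt_start: int,
                    mt_len: int, nuclear_name: str):
    """Alignment of a read from the inserted haplotype against the
    insertion-free reference, mimicking a soft-clipping aligner."""
    a = max(0, min(rl, P - t0))                 # left-flank bases
    b = max(0, min(rl - a, P + size - t0 - a))  # insert bases
    c = rl - a - b                              # right-flank bases
    if b == 0:
        if a == rl:
            return nuclear_name, t0 + 1, f"{rl}M"
        return nuclear_name, t0 - size + 1, f"{rl}M"
    if a >= b and a >= c:
        return nuclear_name, t0 + 1, f"{a}M{b + c}S"
    if c > b:
        return nuclear_name, P + 1, f"{a + b}S{c}M"
    # majority of the read lies in the insert: map to the mt contig
    off0 = t0 + a - P                           # first insert offset covered
    first = mt_start + 1 + off0                 # 1-based, may exceed mt_len
    b1 = min(b, mt_len - ((first - 1) % mt_len))  # bases before the origin
    if b1 >= b:
        pos = circular_position(first, mt_len)
        left, right = a, c
        cigar = (f"{left}S" if left else "") + f"{b}M" + \
            (f"{right}S" if right else "")
        return "chrM", pos, cigar
    b2 = b - b1
    if b1 >= b2:
        pos = circular_position(first, mt_len)
        cigar = (f"{a}S" if a else "") + f"{b1}M" + f"{b2 + c}S"
        return "chrM", pos, cigar
    cigar = f"{a + b1}S" + f"{b2}M" + (f"{c}S" if c else "")
    return "chrM", 1, cigar


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_calls(calls: Sequence, ledger: TruthLedger,
                exclude_blacklisted: bool = True) -> dict:
    """TPR / PPV / F1 per variant type plus planted-vs-called VAF pairs.

    A call is a true positive iff its position, reference and alternative
    alleles all match a planted variant.  Calls flagged as blacklisted are
    excluded before scoring, mirroring the blacklist applied when the
    panel was planted.
    """
    usable = [c for c in calls
              if not (exclude_blacklisted and c.filter == "blacklist")]
    truth = {v.key(): v for v in ledger.variants}
    out: dict = {}
    pairs: List[Tuple[float, float]] = []
    for vtype in (SNV, INS, DEL):
        t_keys = {k for k, v in truth.items() if v.vtype == vtype}
        c_here = [c for c in usable if c.vtype == vtype]
        tp_keys = {(c.pos, c.ref, c.alt) for c in c_here} & t_keys
        n_tp = len(tp_keys)
        n_fp = len([c for c in c_here
                    if (c.pos, c.ref, c.alt) not in t_keys])
        n_fn = len(t_keys) - n_tp
        tpr = n_tp / len(t_keys) if t_keys else float("nan")
        ppv = n_tp / (n_tp + n_fp) if (n_tp + n_fp) else float("nan")
        f1 = (2 * ppv * tpr / (ppv + tpr)
              if n_tp and np.isfinite(ppv) and np.isfinite(tpr)
              and (ppv + tpr) > 0 else 0.0)
        out[vtype] = {"tpr": tpr, "ppv": ppv, "f1": f1,
                      "tp": n_tp, "fp": n_fp, "fn": n_fn}
        for c in c_here:
            v = truth.get((c.pos, c.ref, c.alt))
            if v is not None:
                pairs.append((v.vaf, c.vaf))
    out["pairs"] = pairs
    if len(pairs) >= 2 and len({p[0] for p in pairs}) > 1:
        r, _ = pearsonr([p[0] for p in pairs], [p[1] for p in pairs])
        out["pearson_r"] = float(r)
    else:
        out["pearson_r"] = float("nan")
    return out
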