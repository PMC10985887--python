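"""Reference model, coordinate arithmetic and readers/writers.

The mitochondrial genome is a circular molecule; the human reference
(rCRS-like) is 16,569 bp with a placeholder 'N' at position 3107.  All
user-facing coordinates are 1-based inclusive (VCF style); internal array
indices are 0-based half-open.  Segments of the circle are described by a
``(start, end]`` convention: the transferred segment excludes the start
coordinate and includes the end coordinate, so a segment whose start is
numerically larger than its end spans the artificial break at the origin.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pysam

MT_LENGTH = 16569
MT_PLACEHOLDER_POS = 3107  # 'N' in the rCRS
MT_NAME = "chrM"

BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """Encode a base string as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode_seq(codes: np.ndarray) -> str:
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[np.asarray(codes, dtype=np.uint8)][::-1]


def revcomp(seq: str) -> str:
    return decode_seq(revcomp_codes(encode_seq(seq)))


# ---------------------------------------------------------------------------
# Circular coordinate arithmetic
# ---------------------------------------------------------------------------

def mt_segment_length(start: int, end: int, length: int = MT_LENGTH) -> int:
    """Size of a circular segment under the (start, end] convention.

    The segment excludes ``start`` and includes ``end``; a segment with
    ``start > end`` wraps across the origin.  ``start == end`` denotes the
    full circle.  The two arcs ``(a, b]`` and ``(b, a]`` partition the
    circle, so their sizes always sum to ``length``.
    """
    for name, value in (("start", start), ("end", end)):
        if not 1 <= value <= length:
            raise ValueError(f"{name}={value} outside [1, {length}]")
    if end > start:
        return end - start
    return (length - start) + end


def circular_distance(a: int, b: int, length: int = MT_LENGTH) -> int:
    """Shortest distance between two positions on the circle."""
    d = abs(int(a) - int(b))
    return min(d, length - d)


def circular_position(pos: int, length: int = MT_LENGTH) -> int:
    """Map an arbitrary integer onto 1..length."""
    return (int(pos) - 1) % length + 1


def in_circular_segment(pos: int, start: int, end: int,
                        length: int = MT_LENGTH) -> bool:
    """Membership of ``pos`` in the segment (start, end] on the circle."""
    pos = circular_position(pos, length)
    if end > start:
        return start < pos <= end
    return pos > start or pos <= end


# ---------------------------------------------------------------------------
# Reference sequence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircularReference:
    """A (possibly circular) reference contig held in memory."""

    name: str
    sequence: str
    is_circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("empty reference sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        # cached lazily on first use
        cached = self.__dict__.get("_codes")
        if cached is None:
            cached = encode_seq(self.sequence)
            object.__setattr__(self, "_codes", cached)
        return cached

    def base(self, pos: int) -> str:
        """1-based single-base access (wraps if circular)."""
        if self.is_circular:
            pos = circular_position(pos, self.length)
        if not 1 <= pos <= self.length:
            raise ValueError(f"position {pos} outside contig {self.name}")
        return self.sequence[pos - 1]

    def segment(self, start: int, end: int) -> str:
        """Bases of the circular segment (start, end]."""
        size = mt_segment_length(start, end, self.length)
        doubled = self.sequence + self.sequence
        return doubled[start:start + size]

    def context(self, pos: int) -> str:
        """Trinucleotide context centred on ``pos`` (circular wrap)."""
        if self.is_circular:
            return (self.base(pos - 1) + self.base(pos) + self.base(pos + 1))
        if pos == 1 or pos == self.length:
            return "N" + self.base(pos) + "N"
        return self.sequence[pos - 2:pos + 1]

    def doubled(self) -> str:
        return self.sequence + self.sequence

    @classmethod
    def from_fasta(cls, path: str, name: Optional[str] = None,
                   is_circular: bool = True) -> "CircularReference":
        with pysam.FastxFile(str(path)) as fh:
            for entry in fh:
                if name is None or entry.name == name:
                    return cls(entry.name, entry.sequence, is_circular)
        raise ValueError(f"contig {name!r} not found in {path}")

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for i in range(0, self.length, 70):
                fh.write(self.sequence[i:i + 70] + "\n")

    @classmethod
    def random_mt(cls, seed: int, length: int = MT_LENGTH,
                  name: str = MT_NAME,
                  placeholder_pos: Optional[int] = MT_PLACEHOLDER_POS
                  ) -> "CircularReference":
        """A seeded random circular genome mirroring the rCRS layout.

        Used by tests and the simulator so that no reference download is
        ever required.  When ``length`` matches the mitochondrial genome a
        placeholder 'N' is written at the rCRS gap position.
        """
        rng = np.random.default_rng(seed)
        codes = rng.integers(0, 4, size=length, dtype=np.uint8)
        seq = list(decode_seq(codes))
        if placeholder_pos is not None and 1 <= placeholder_pos <= length:
            seq[placeholder_pos - 1] = "N"
        return cls(name, "".join(seq), is_circular=True)

    @classmethod
    def random_nuclear(cls, seed: int, length: int,
                       name: str = "chr1") -> "CircularReference":
        rng = np.random.default_rng(seed)
        codes = rng.integers(0, 4, size=length, dtype=np.uint8)
        return cls(name, decode_seq(codes), is_circular=False)


# ---------------------------------------------------------------------------
# Blacklist
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Blacklist:
    """Artifact-prone positions excluded from simulation and flagged in calls.

    Intervals are 1-based inclusive.  The default mitochondrial blacklist is
    the two artifact-prone runs 300-317 and 16180-16193 plus the placeholder
    position 3107.
    """

    intervals: tuple = ()
    single_positions: tuple = ()
    contig: str = MT_NAME

    @classmethod
    def default_mt(cls) -> "Blacklist":
        return cls(intervals=((300, 317), (16180, 16193)),
                   single_positions=(3107,))

    def contains(self, pos: int) -> bool:
        if pos in self.single_positions:
            return True
        return any(s <= pos <= e for s, e in self.intervals)

    def positions(self) -> frozenset:
        out = set(self.single_positions)
        for s, e in self.intervals:
            out.update(range(s, e + 1))
        return frozenset(out)

    def to_bed(self, path: str) -> None:
        """BED is 0-based half-open."""
        with open(path, "w") as fh:
            for s, e in self.intervals:
                fh.write(f"{self.contig}\t{s - 1}\t{e}\n")
            for p in self.single_positions:
                fh.write(f"{self.contig}\t{p - 1}\t{p}\n")

    @classmethod
    def from_bed(cls, path: str) -> "Blacklist":
        intervals = []
        contig = MT_NAME
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                contig, s, e = fields[0], int(fields[1]), int(fields[2])
                intervals.append((s + 1, e))
        singles = tuple(s for s, e in intervals if s == e)
        ivals = tuple((s, e) for s, e in intervals if s != e)
        return cls(intervals=ivals, single_positions=singles, contig=contig)


# ---------------------------------------------------------------------------
# Aligned reads
# ---------------------------------------------------------------------------

_CIGAR_QUERY_OPS = set("MIS=X")
_CIGAR_REF_OPS = set("MD=XN")


def parse_cigar(cigar: str) -> list:
    """Parse a CIGAR string into (op, length) tuples."""
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if not num:
                raise ValueError(f"malformed CIGAR {cigar!r}")
            out.append((ch, int(num)))
            num = ""
    if num:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return out


def cigar_query_length(cigar: str) -> int:
    return sum(n for op, n in parse_cigar(cigar) if op in _CIGAR_QUERY_OPS)


def cigar_reference_span(cigar: str) -> int:
    return sum(n for op, n in parse_cigar(cigar) if op in _CIGAR_REF_OPS)


@dataclass
class AlignedRead:
    """A single alignment record (SAM semantics, 1-based leftmost position)."""

    qname: str
    contig: str
    pos: int                      # 1-based leftmost mapped position
    mapq: int
    cigar: str
    seq: str
    qual: np.ndarray              # Phred values, one per base
    is_reverse: bool = False
    is_paired: bool = True
    is_proper_pair: bool = True
    is_duplicate: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    mate_contig: Optional[str] = None
    mate_pos: Optional[int] = None

    def __post_init__(self) -> None:
        self.qual = np.asarray(self.qual, dtype=np.uint8)
        if cigar_query_length(self.cigar) != len(self.seq):
            raise ValueError(
                f"CIGAR {self.cigar} inconsistent with {len(self.seq)}-bp read")
        if len(self.qual) != len(self.seq):
            raise ValueError("quality length differs from sequence length")

    @property
    def strand(self) -> str:
        return "-" if self.is_reverse else "+"

    def reference_end(self) -> int:
        """1-based inclusive rightmost mapped position."""
        return self.pos + cigar_reference_span(self.cigar) - 1

    def aligned_bases(self):
        """Yield per-base evidence and indel events from the CIGAR walk.

        Returns ``(positions, base_codes, quals, indels)`` where positions
        are 1-based reference coordinates of aligned (M/=/X) bases and
        indels is a list of ``(anchor_pos, kind, alt)`` with kind 'INS'
        (alt = inserted bases) or 'DEL' (alt = deletion length).
        """
        codes = encode_seq(self.seq)
        positions, bases, quals, indels = [], [], [], []
        rpos = self.pos
        qpos = 0
        for op, n in parse_cigar(self.cigar):
            if op in "M=X":
                positions.append(np.arange(rpos, rpos + n))
                bases.append(codes[qpos:qpos + n])
                quals.append(self.qual[qpos:qpos + n])
                rpos += n
                qpos += n
            elif op == "I":
                indels.append((rpos - 1, "INS", self.seq[qpos:qpos + n]))
                qpos += n
            elif op == "D":
                indels.append((rpos - 1, "DEL", n))
                rpos += n
            elif op == "S":
                qpos += n
            elif op == "N":
                rpos += n
            elif op == "H":
                pass
            else:
                raise ValueError(f"unsupported CIGAR op {op}")
        if positions:
            return (np.concatenate(positions), np.concatenate(bases),
                    np.concatenate(quals), indels)
        return (np.empty(0, dtype=int), np.empty(0, dtype=np.uint8),
                np.empty(0, dtype=np.uint8), indels)

    def soft_clips(self):
        """Return [(side, length, seq)] for soft-clipped ends ('L'/'R')."""
        ops = parse_cigar(self.cigar)
        out = []
        if ops and ops[0][0] == "S":
            out.append(("L", ops[0][1], self.seq[:ops[0][1]]))
        if len(ops) > 1 and ops[-1][0] == "S":
            out.append(("R", ops[-1][1], self.seq[-ops[-1][1]:]))
        return out

    # -- pysam conversion ---------------------------------------------------

    @classmethod
    def from_pysam(cls, rec: "pysam.AlignedSegment") -> "AlignedRead":
        qual = rec.query_qualities
        return cls(
            qname=rec.query_name,
            contig=rec.reference_name,
            pos=rec.reference_start + 1,
            mapq=rec.mapping_quality,
            cigar=rec.cigarstring,
            seq=rec.query_sequence,
            qual=np.array(qual, dtype=np.uint8) if qual is not None
            else np.zeros(len(rec.query_sequence), dtype=np.uint8),
            is_reverse=rec.is_reverse,
            is_paired=rec.is_paired,
            is_proper_pair=rec.is_proper_pair,
            is_duplicate=rec.is_duplicate,
            is_secondary=rec.is_secondary,
            is_supplementary=rec.is_supplementary,
            mate_contig=rec.next_reference_name if rec.is_paired else None,
            mate_pos=rec.next_reference_start + 1
            if rec.is_paired and rec.next_reference_start >= 0 else None,
        )

    def to_pysam(self, header: "pysam.AlignmentHeader") -> "pysam.AlignedSegment":
        rec = pysam.AlignedSegment(header)
        rec.query_name = self.qname
        rec.reference_id = header.get_tid(self.contig)
        rec.reference_start = self.pos - 1
        rec.mapping_quality = self.mapq
        rec.cigarstring = self.cigar
        rec.query_sequence = self.seq
        rec.query_qualities = self.qual.tolist()
        rec.is_paired = self.is_paired
        rec.is_reverse = self.is_reverse
        rec.is_proper_pair = self.is_proper_pair
        rec.is_duplicate = self.is_duplicate
        rec.is_secondary = self.is_secondary
        rec.is_supplementary = self.is_supplementary
        if self.mate_contig is not None:
            rec.next_reference_id = header.get_tid(self.mate_contig)
            rec.next_reference_start = (self.mate_pos or 1) - 1
            rec.mate_is_reverse = not self.is_reverse
        else:
            rec.next_reference_id = -1
            rec.next_reference_start = -1
        return rec


def make_header(ref_lengths: dict) -> "pysam.AlignmentHeader":
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": int(length)}
               for name, length in ref_lengths.items()],
    })


def write_alignments(reads: Iterable[AlignedRead], path: str,
                     ref_lengths: dict) -> None:
    """Write records coordinate-sorted as SAM or BAM (by extension).

    BAM output is indexed in place so that region queries work immediately.
    """
    header = make_header(ref_lengths)
    order = {name: i for i, name in enumerate(ref_lengths)}
    records = sorted(reads, key=lambda r: (order[r.contig], r.pos, r.qname))
    mode = "wb" if str(path).endswith(".bam") else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for read in records:
            out.write(read.to_pysam(header))
    if mode == "wb":
        pysam.index(str(path))


def read_alignments(path: str, contig: Optional[str] = None,
                    start: Optional[int] = None,
                    end: Optional[int] = None) -> Iterator[AlignedRead]:
    """Stream alignment records, optionally restricted to a 1-based region.

    Secondary/supplementary and duplicate records are yielded with their
    flags set rather than silently dropped.  BAM region queries require an
    index; SAM input is scanned linearly and must be coordinate-sorted.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    is_bam = str(path).endswith(".bam")
    save = pysam.set_verbosity(0)
    af = pysam.AlignmentFile(str(path), "rb" if is_bam else "r")
    pysam.set_verbosity(save)
    try:
        lengths = dict(zip(af.references, af.lengths))
        if contig is not None:
            if contig not in lengths:
                raise ValueError(f"unknown contig {contig!r}")
            clen = lengths[contig]
            if start is not None and end is not None and start > end:
                return  # empty region is vacuously fine
            for bound in (start, end):
                if bound is not None and not 1 <= bound <= clen:
                    raise ValueError(
                        f"region bound {bound} outside contig {contig} "
                        f"(length {clen})")
        if is_bam and contig is not None:
            if not af.has_index():
                raise ValueError(f"{path} has no index; run samtools index")
            for rec in af.fetch(contig, (start or 1) - 1, end or lengths[contig]):
                yield AlignedRead.from_pysam(rec)
        else:
            so = (af.header.to_dict().get("HD") or {}).get("SO")
            if so not in (None, "coordinate"):
                raise ValueError(f"{path} is not coordinate-sorted (SO={so})")
            last = {}
            for rec in af:
                if rec.is_unmapped:
                    continue
                name = rec.reference_name
                if rec.reference_start < last.get(name, 0):
                    raise ValueError(f"{path} is not coordinate-sorted")
                last[name] = rec.reference_start
                if contig is not None:
                    if name != contig:
                        continue
                    if end is not None and rec.reference_start + 1 > end:
                        continue
                    if start is not None and rec.reference_end < start:
                        continue
                yield AlignedRead.from_pysam(rec)
    finally:
        af.close()


# ---------------------------------------------------------------------------
# Variant calls and VCF I/O
# ---------------------------------------------------------------------------

SNV, INS, DEL = "SNV", "INS", "DEL"


@dataclass
class VariantCall:
    """One mitochondrial variant with its supporting evidence.

    Indels use the VCF anchor convention: ``pos`` is the base before the
    event, ``ref``/``alt`` include the anchor base.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    vtype: str                    # SNV / INS / DEL
    vaf: float
    depth: int = 0                # consensus (template-level) depth
    fwd_support: int = 0
    rev_support: int = 0
    p_value: float = float("nan")
    source: str = "dmtlv"         # round-1 / round-2 / external merge
    filter: str = "PASS"
    indel_support: int = 0        # consensus sequences carrying the indel

    def key(self):
        return (self.contig, self.pos, self.ref, self.alt)


_VCF_INFO = [
    ("VAF", "1", "Float", "Variant allele fraction"),
    ("DP", "1", "Integer", "Template-level depth"),
    ("ADF", "1", "Integer", "Forward-strand support"),
    ("ADR", "1", "Integer", "Reverse-strand support"),
    ("VT", "1", "String", "Variant type (SNV/INS/DEL)"),
    ("PG", "1", "Float", "Likelihood-ratio test p-value"),
    ("SRC", "1", "String", "Provenance (caller round or merge source)"),
    ("ISUP", "1", "Integer", "Consensus sequences supporting the indel"),
]


def write_variants(calls: Sequence[VariantCall], path: str,
                   contigs: dict) -> None:
    """Emit calls as VCF; round-trips losslessly through read_variants."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=int(length))
    for vid, num, vtype, desc in _VCF_INFO:
        header.info.add(vid, num, vtype, desc)
    header.filters.add("blacklist", None, None, "Artifact-prone position")
    for call in calls:
        if call.contig not in contigs:
            raise ValueError(f"unknown contig {call.contig!r}")
        if call.pos > contigs[call.contig]:
            raise ValueError(
                f"position {call.pos} beyond contig {call.contig} end")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in sorted(calls, key=lambda c: (c.contig, c.pos, c.alt)):
            rec = out.new_record(
                contig=call.contig, start=call.pos - 1,
                stop=call.pos - 1 + len(call.ref),
                alleles=(call.ref, call.alt))
            rec.info["VAF"] = round(float(call.vaf), 6)
            rec.info["DP"] = int(call.depth)
            rec.info["ADF"] = int(call.fwd_support)
            rec.info["ADR"] = int(call.rev_support)
            rec.info["VT"] = call.vtype
            if np.isfinite(call.p_value):
                rec.info["PG"] = float(call.p_value)
            rec.info["SRC"] = call.source
            if call.indel_support:
                rec.info["ISUP"] = int(call.indel_support)
            rec.filter.add(call.filter if call.filter else "PASS")
            out.write(rec)


def read_variants(path: str) -> list:
    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            pg = info.get("PG")
            calls.append(VariantCall(
                contig=rec.contig, pos=rec.pos,
                ref=rec.ref, alt=rec.alts[0],
                vtype=info.get("VT", SNV),
                vaf=round(float(info.get("VAF", 0.0)), 6),
                depth=int(info.get("DP", 0)),
                fwd_support=int(info.get("ADF", 0)),
                rev_support=int(info.get("ADR", 0)),
                p_value=float(pg) if pg is not None else float("nan"),
                source=info.get("SRC", "dmtlv"),
                filter=";".join(rec.filter.keys()) or "PASS",
                indel_support=int(info.get("ISUP", 0)),
            ))
    return calls


# ---------------------------------------------------------------------------
# Compact read container for deep pileups
# ---------------------------------------------------------------------------

@dataclass
class ReadBlock:
    """Column-oriented container for uniform-length paired reads.

    The simulator emits this directly and the heteroplasmy caller consumes
    it, so deep mtDNA pileups (5,000-20,000x) never materialise per-read
    Python objects.  Reads come in fragment pairs: ``frag_id[i]`` links the
    two mates; mate 1 is the leftmost (forward) read.
    """

    contig: str
    read_len: int
    pos: np.ndarray               # (n,) int64, 0-based leftmost
    strand: np.ndarray            # (n,) uint8, 0 forward / 1 reverse
    mapq: np.ndarray              # (n,) uint8
    seq: np.ndarray               # (n, read_len) uint8 codes
    qual: np.ndarray              # (n, read_len) uint8 Phred
    cigar_id: np.ndarray          # (n,) int32 into cigars
    cigars: list                  # cigars[0] == f"{read_len}M"
    frag_id: np.ndarray           # (n,) int64
    origin: Optional[np.ndarray] = None   # simulator labels (0 wild, 1 mutated)

    @property
    def n_reads(self) -> int:
        return len(self.pos)

    def family_keys(self):
        """Per-fragment family assignment.

        Fragments sharing both mates' positions and CIGAR strings form one
        read family (duplicate templates).  Returns ``(frag_ids, fam_of_frag,
        n_families)`` where ``fam_of_frag`` maps each distinct fragment to a
        family index.
        """
        order = np.lexsort((self.pos, self.frag_id))
        fid = self.frag_id[order]
        pos = self.pos[order]
        cig = self.cigar_id[order]
        uniq_f, first = np.unique(fid, return_index=True)
        # mates per fragment, ordered by position
        p1, p2 = pos[first], pos[first + 1]
        c1, c2 = cig[first], cig[first + 1]
        key = np.rec.fromarrays([p1, p2, c1, c2],
                                names="p1,p2,c1,c2")
        _, fam = np.unique(key, return_inverse=True)
        return uniq_f, fam, int(fam.max()) + 1 if len(fam) else 0

    def to_reads(self) -> Iterator[AlignedRead]:
        for i in range(self.n_reads):
            yield AlignedRead(
                qname=f"frag{self.frag_id[i]}",
                contig=self.contig,
                pos=int(self.pos[i]) + 1,
                mapq=int(self.mapq[i]),
                cigar=self.cigars[self.cigar_id[i]],
                seq=decode_seq(self.seq[i]),
                qual=self.qual[i].copy(),
                is_reverse=bool(self.strand[i]),
            )

    def to_alignment_file(self, path: str,
                          ref_lengths: Optional[dict] = None) -> None:
        if ref_lengths is None:
            ref_lengths = {self.contig: int(self.pos.max()) + 2 * self.read_len}
        header = make_header(ref_lengths)
        order = np.lexsort((self.frag_id, self.pos))
        mode = "wb" if str(path).endswith(".bam") else "w"
        mate = _mate_index(self.frag_id)
        with pysam.AlignmentFile(str(path), mode, header=header) as out:
            for i in order:
                rec = pysam.AlignedSegment(header)
                rec.query_name = f"frag{self.frag_id[i]}"
                rec.reference_id = header.get_tid(self.contig)
                rec.reference_start = int(self.pos[i])
                rec.mapping_quality = int(self.mapq[i])
                rec.cigarstring = self.cigars[self.cigar_id[i]]
                rec.query_sequence = decode_seq(self.seq[i])
                rec.query_qualities = self.qual[i].tolist()
                rec.is_paired = True
                rec.is_proper_pair = True
                rec.is_reverse = bool(self.strand[i])
                rec.is_read1 = not bool(self.strand[i])
                rec.is_read2 = bool(self.strand[i])
                rec.mate_is_reverse = not bool(self.strand[i])
                rec.next_reference_id = rec.reference_id
                rec.next_reference_start = int(self.pos[mate[i]])
                out.write(rec)
        if mode == "wb":
            pysam.index(str(path))

    @classmethod
    def from_reads(cls, reads: Iterable[AlignedRead], contig: str,
                   read_len: int) -> "ReadBlock":
        """Build a block from paired records of one uniform read length."""
        by_name: dict = {}
        for read in reads:
            if read.contig != contig or read.is_secondary or read.is_supplementary:
                continue
            by_name.setdefault(read.qname, []).append(read)
        pos, strand, mapq, seqs, quals, cigid, fragid = [], [], [], [], [], [], []
        cigars = [f"{read_len}M"]
        cigar_index = {cigars[0]: 0}
        for fi, (name, mates) in enumerate(sorted(by_name.items())):
            for read in mates:
                if len(read.seq) != read_len:
                    raise ValueError("ReadBlock requires uniform read length")
                pos.append(read.pos - 1)
                strand.append(1 if read.is_reverse else 0)
                mapq.append(read.mapq)
                seqs.append(encode_seq(read.seq))
                quals.append(read.qual)
                if read.cigar not in cigar_index:
                    cigar_index[read.cigar] = len(cigars)
                    cigars.append(read.cigar)
                cigid.append(cigar_index[read.cigar])
                fragid.append(fi)
            if len(mates) == 1:   # synthesise a missing mate marker
                pass
        return cls(
            contig=contig, read_len=read_len,
            pos=np.array(pos, dtype=np.int64),
            strand=np.array(strand, dtype=np.uint8),
            mapq=np.array(mapq, dtype=np.uint8),
            seq=np.vstack(seqs).astype(np.uint8),
            qual=np.vstack(quals).astype(np.uint8),
            cigar_id=np.array(cigid, dtype=np.int32),
            cigars=cigars,
            frag_id=np.array(fragid, dtype=np.int64),
        )


def _mate_index(frag_id: np.ndarray) -> np.ndarray:
    """Index of each read's mate, assuming exactly two reads per fragment."""
    order = np.argsort(frag_id, kind="stable")
    mate = np.empty_like(order)
    mate[order[0::2]] = order[1::2]
    mate[order[1::2]] = order[0::2]
    return mate
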