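"""mtDNA copy number, sample-specific variant filters, mutational spectrum.

mtCN is estimated from the depth ratio between the mitochondrial and the
nuclear genome, corrected for tumor purity and ploidy:

    mtCN = (mt coverage / mean autosomal coverage)
           x (purity x ploidy + (1 - purity) x 2)

A non-reference NUMT adds one (heterozygous) or two (homozygous) nuclear
copies of its segment per cell, so misaligned NUMT reads produce apparent
mtDNA variants at an expected VAF of 1/(1 + mtCN) or 2/(2 + mtCN); calls
matching an identified NUMT mismatch whose VAF sits near or below that
threshold are removed.  Independently, any call with VAF below 1/mtCN is
supported by less than one mtDNA copy per cell and is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .reference import (
    SNV, CircularReference, VariantCall, in_circular_segment, revcomp,
)

SIX_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
PYRIMIDINES = {"C", "T"}


# ---------------------------------------------------------------------------
# mtDNA copy number
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MtCNRecord:
    sample_id: str
    mt_coverage: float
    autosomal_coverage: float
    purity: float
    ploidy: float
    mtcn: float
    role: str = "normal"          # normal / tumor


def compute_mtcn(mt_coverage: float, autosomal_coverage: float,
                 purity: float = 1.0, ploidy: float = 2.0,
                 sample_id: str = "sample",
                 role: str = "normal") -> MtCNRecord:
    """Purity/ploidy-corrected mitochondrial copy number.

    Normal samples use purity 1 and ploidy 2, which reduces the correction
    factor to 2 (two autosomal copies per cell).
    """
    if mt_coverage <= 0 or autosomal_coverage <= 0:
        raise ValueError("coverages must be positive")
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must lie in (0, 1]")
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    factor = purity * ploidy + (1.0 - purity) * 2.0
    mtcn = mt_coverage / autosomal_coverage * factor
    return MtCNRecord(sample_id, mt_coverage, autosomal_coverage,
                      purity, ploidy, mtcn, role)


@dataclass(frozen=True)
class TnRatio:
    patient_id: str
    tumor_mtcn: float
    normal_mtcn: float

    @property
    def ratio(self) -> float:
        return self.tumor_mtcn / self.normal_mtcn


def tn_ratio(tumor: MtCNRecord, normal: MtCNRecord,
             patient_id: str = "patient") -> TnRatio:
    if normal.mtcn <= 0:
        raise ValueError("normal mtCN must be positive")
    return TnRatio(patient_id, tumor.mtcn, normal.mtcn)


def mean_coverage(depths: np.ndarray) -> float:
    """Mean over all positions of the contig, zero-depth included."""
    return float(np.asarray(depths, dtype=float).mean())


# ---------------------------------------------------------------------------
# NUMT-FP and copy-number floor filters
# ---------------------------------------------------------------------------

def numtfp_vaf_threshold(mtcn: float, zygosity: str) -> float:
    """Expected VAF of variants arising from a non-ref NUMT copy."""
    if mtcn <= 0:
        raise ValueError("mtCN must be positive")
    if zygosity not in ("het", "hom"):
        raise ValueError(f"unknown zygosity {zygosity!r}")
    return 1.0 / (1.0 + mtcn) if zygosity == "het" else 2.0 / (2.0 + mtcn)


@dataclass
class RemovalRecord:
    call: VariantCall
    reason: str


def filter_numtfp(calls: Sequence[VariantCall], numt_calls: Sequence,
                  fps: Sequence, mtcn: float,
                  mt_length: int = 16569
                  ) -> Tuple[List[VariantCall], List[RemovalRecord]]:
    """Remove calls attributable to non-reference NUMT copies.

    A call inside an inserted segment is removed iff it matches an
    identified mismatch AND its VAF is near or below the zygosity-derived
    threshold: (VAF - threshold) / threshold < 1 (signed, so calls far
    above threshold are always retained).  For segments whose assembly is
    incomplete, the VAF criterion alone applies within the unassembled
    region.  Returns the retained calls and a removal ledger.
    """
    fp_keys = {(f.mt_pos, f.obs) for f in fps}
    kept: List[VariantCall] = []
    removed: List[RemovalRecord] = []
    for call in calls:
        verdict: Optional[str] = None
        for numt in numt_calls:
            if not in_circular_segment(call.pos, numt.mt_start, numt.mt_end,
                                       mt_length):
                continue
            threshold = numtfp_vaf_threshold(mtcn, numt.zygosity or "het")
            near = (call.vaf - threshold) / threshold < 1.0
            alt_base = call.alt[-1] if call.vtype != SNV else call.alt
            is_mismatch = (call.pos, alt_base) in fp_keys \
                or (call.pos, call.alt) in fp_keys
            if is_mismatch and near:
                verdict = (f"numt_fp:mismatch,vaf={call.vaf:.4g},"
                           f"thr={threshold:.4g}")
                break
            if not numt.assembled and not is_mismatch and near:
                # unassembled region: mismatch status is unknowable
                verdict = (f"numt_fp:unassembled,vaf={call.vaf:.4g},"
                           f"thr={threshold:.4g}")
                break
        if verdict is None:
            kept.append(call)
        else:
            removed.append(RemovalRecord(call, verdict))
    return kept, removed


def filter_mtcn_floor(calls: Sequence[VariantCall], mtcn: float
                      ) -> Tuple[List[VariantCall], List[RemovalRecord]]:
    """Remove calls with VAF strictly below 1/mtCN.

    Below one mtDNA copy per cell the call cannot represent a real
    heteroplasmy; the boundary VAF = 1/mtCN is retained.
    """
    if mtcn <= 0:
        raise ValueError("mtCN must be positive")
    floor = 1.0 / mtcn
    kept, removed = [], []
    for call in calls:
        if call.vaf < floor:
            removed.append(RemovalRecord(
                call, f"below_mtcn_floor:vaf={call.vaf:.4g},floor={floor:.4g}"))
        else:
            kept.append(call)
    return kept, removed


# ---------------------------------------------------------------------------
# Mutational spectrum
# ---------------------------------------------------------------------------

@dataclass
class SpectrumCounts:
    """Six-type and 96-trinucleotide-context substitution counts.

    ``six`` and ``contexts`` are pyrimidine-strand collapsed (the
    convention of mutational-signature analysis); ``raw_twelve`` keeps the
    uncollapsed strand-specific counts.  SNVs whose context contains an
    undetermined base land in ``undetermined`` rather than being dropped.
    """

    six: Dict[str, int] = field(default_factory=dict)
    contexts: Dict[str, int] = field(default_factory=dict)
    raw_twelve: Dict[str, int] = field(default_factory=dict)
    undetermined: int = 0

    @property
    def total(self) -> int:
        return sum(self.six.values()) + self.undetermined

    def proportions(self) -> Dict[str, float]:
        total = sum(self.six.values())
        return {k: v / total for k, v in self.six.items()} if total else {}


def collapse_substitution(ref: str, alt: str) -> Tuple[str, bool]:
    """Map a substitution to its pyrimidine-strand class.

    Returns (class, flipped): purine references are complemented, e.g.
    G>T counts as C>A.
    """
    if ref in PYRIMIDINES:
        return f"{ref}>{alt}", False
    return f"{revcomp(ref)}>{revcomp(alt)}", True


def count_spectrum(calls: Sequence[VariantCall],
                   reference: CircularReference) -> SpectrumCounts:
    """Tally SNVs into 6 substitution types and 96 trinucleotide contexts.

    The trinucleotide context comes from the reference with circular wrap
    at the origin; counts conserve the number of SNVs.
    """
    out = SpectrumCounts(six={t: 0 for t in SIX_TYPES}, contexts={},
                         raw_twelve={})
    for call in calls:
        if call.vtype != SNV or len(call.ref) != 1 or len(call.alt) != 1:
            continue
        ref, alt = call.ref, call.alt
        tri = reference.context(call.pos)
        if "N" in (ref + alt) or "N" in tri:
            out.undetermined += 1
            continue
        raw = f"{ref}>{alt}"
        out.raw_twelve[raw] = out.raw_twelve.get(raw, 0) + 1
        sub, flipped = collapse_substitution(ref, alt)
        out.six[sub] += 1
        context = revcomp(tri) if flipped else tri
        key = f"{context[0]}[{sub}]{context[2]}"
        out.contexts[key] = out.contexts.get(key, 0) + 1
    return out


# ---------------------------------------------------------------------------
# Truncating-mutation burden
# ---------------------------------------------------------------------------

TRUNCATING = {"stop-gain", "frameshift"}


def max_truncating_vaf(calls: Sequence[VariantCall],
                       consequences: Dict[tuple, str]) -> dict:
    """Per-sample max and mean VAF over truncating mutations.

    ``consequences`` maps (pos, ref, alt) to an externally supplied
    consequence label; stop-gain SNVs and frameshift indels count.  With
    no truncating call both statistics are 0 and flagged absent.
    """
    vafs = [c.vaf for c in calls
            if consequences.get((c.pos, c.ref, c.alt)) in TRUNCATING]
    if not vafs:
        return {"max_tvaf": 0.0, "mean_tvaf": 0.0, "n": 0, "present": False}
    return {"max_tvaf": float(max(vafs)),
            "mean_tvaf": float(np.mean(vafs)),
            "n": len(vafs), "present": True}
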