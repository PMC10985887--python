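"""Two-round likelihood-ratio caller for low-heteroplasmy mtDNA variants.

The caller models sequencing error and PCR error separately.  Round one
tests, per position and per strand, whether an allele's fraction exceeds
zero given each read's base-quality-derived error probability: a read
showing allele ``g`` is observed with probability

    P(x_i | theta) = (1 - e_i) * theta_g + (e_i / 3) * (1 - theta_g)

and the log-likelihood is maximised over ``theta_g`` in [0, 1].  Because
the null (theta_g = 0) sits on the boundary of the parameter space, the
statistic ``t_g = -2 (l0 - l1)`` is referred to the 50:50 mixture of a
point mass at zero and chi-square with one degree of freedom.

Alleles that fail on either strand are masked to 'N'; reads sharing both
mates' coordinates and CIGAR strings (duplicate templates) collapse into
consensus sequences whose per-base quality combines the residual
sequencing error with a coalescent PCR error term:

    Q(g) = -10 log10(P_c(g) + P_pcr(g)),     P_pcr(g) ~ n * e_pcr(g)^2
    e_pcr = 1 - (1 - per-cycle error)^(2^m - 1)

Round two repeats the likelihood test over consensus sequences, which
yields the final calls; indels are selected by maximum consensus support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .reference import (
    DEL, INS, SNV, AlignedRead, Blacklist, CircularReference, ReadBlock,
    VariantCall, decode_seq,
)

# Defaults: the test level matches the error-rate regime in which the
# p-value is a good estimate of the per-allele error rate; base/mapping
# quality admission and the PCR fidelity range follow the method design.
ALPHA = 1e-3
MIN_BASE_QUALITY = 20          # strict: bases must exceed this
MIN_MAPPING_QUALITY = 30
ERROR_FLOOR = 1e-4             # floor on per-read error probabilities
QMAX = 64                      # quality axis size for binned pileups
MAX_QUALITY = 93               # Phred+33 encodable ceiling


def phred_to_error(qual, floor: float = ERROR_FLOOR) -> np.ndarray:
    e = np.power(10.0, -np.asarray(qual, dtype=float) / 10.0)
    return np.maximum(e, floor) if floor else e


def error_levels(floor: float = ERROR_FLOOR) -> np.ndarray:
    return phred_to_error(np.arange(QMAX), floor)


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

def support_probability(e_i, theta_g):
    """P(read shows g | fraction theta_g, error e_i)."""
    e_i = np.asarray(e_i, dtype=float)
    theta_g = np.asarray(theta_g, dtype=float)
    return (1.0 - e_i) * theta_g + (e_i / 3.0) * (1.0 - theta_g)


def allele_likelihood(x_i: str, e_i: float, theta_g: float) -> float:
    """Probability of observing allele ``x_i`` given its own fraction.

    ``theta_g`` is the allelic fraction of the observed allele ``x_i``.
    """
    if not 0.0 < e_i < 1.0:
        raise ValueError(f"e_i={e_i} outside (0, 1)")
    if not 0.0 <= theta_g <= 1.0:
        raise ValueError(f"theta_g={theta_g} outside [0, 1]")
    if x_i not in "ACGT" and len(x_i) < 1:
        raise ValueError("invalid allele")
    return float(support_probability(e_i, theta_g))


@dataclass
class AlleleObservation:
    allele: str
    error: float
    strand: str = "+"
    family_id: int = 0


@dataclass
class PileupColumn:
    position: int
    ref: str
    observations: List[AlleleObservation]

    @property
    def depth(self) -> int:
        return len(self.observations)


@dataclass
class LrtResult:
    allele: str
    theta_hat: float
    t: float
    p_value: float
    passed: bool
    n_support: int = 0
    depth: int = 0


def _column_loglik(e_sup: np.ndarray, e_oth: np.ndarray, theta: float) -> float:
    ll = 0.0
    if len(e_sup):
        ll += float(np.sum(np.log(support_probability(e_sup, theta))))
    if len(e_oth):
        ll += float(np.sum(np.log1p(-support_probability(e_oth, theta))))
    return ll


def _mixture_p(t: float, boundary_mix: bool) -> float:
    if t <= 0.0:
        return 1.0
    p = float(chi2.sf(t, 1))
    return 0.5 * p if boundary_mix else p


def lrt_allele(column: PileupColumn, g: str, alpha: float = ALPHA,
               boundary_mix: bool = True) -> LrtResult:
    """Likelihood-ratio test for allele ``g`` at one pileup column.

    The fraction of ``g`` is profiled out by 1-D bounded maximisation; the
    other alleles enter through the complementary probability term.  The
    p-value uses the boundary-adjusted chi-square mixture unless
    ``boundary_mix`` is disabled.
    """
    if column.depth == 0:
        raise ValueError("column has no observations")
    e_all = np.array([max(o.error, ERROR_FLOOR) for o in column.observations])
    is_g = np.array([o.allele == g for o in column.observations])
    e_sup, e_oth = e_all[is_g], e_all[~is_g]
    k = int(is_g.sum())
    if k == 0:
        return LrtResult(g, 0.0, 0.0, 1.0, False, 0, column.depth)
    res = minimize_scalar(lambda th: -_column_loglik(e_sup, e_oth, th),
                          bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-10})
    theta_hat = float(res.x)
    ll_hat = -float(res.fun)
    ll0 = _column_loglik(e_sup, e_oth, 0.0)
    if ll0 > ll_hat:          # boundary maximum
        theta_hat, ll_hat = 0.0, ll0
    t = max(0.0, 2.0 * (ll_hat - ll0))
    p = _mixture_p(t, boundary_mix)
    return LrtResult(g, theta_hat, t, p, p <= alpha, k, column.depth)


def lrt_grid_oracle(column: PileupColumn, g: str,
                    step: float = 1e-4) -> Tuple[float, float]:
    """Exhaustive grid maximisation of the column likelihood.

    Independent of the bounded optimiser; used to validate it.
    """
    e_all = np.array([max(o.error, ERROR_FLOOR) for o in column.observations])
    is_g = np.array([o.allele == g for o in column.observations])
    e_sup, e_oth = e_all[is_g], e_all[~is_g]
    grid = np.arange(0.0, 1.0 + step / 2, step)
    p_sup = support_probability(e_sup[None, :], grid[:, None])
    ll = np.sum(np.log(p_sup), axis=1) if len(e_sup) else np.zeros_like(grid)
    if len(e_oth):
        p_oth = support_probability(e_oth[None, :], grid[:, None])
        ll = ll + np.sum(np.log1p(-p_oth), axis=1)
    best = int(np.argmax(ll))
    t = max(0.0, 2.0 * (ll[best] - ll[0]))
    return float(grid[best]), float(t)


def _batch_lrt(k: np.ndarray, n: np.ndarray, e_lv: np.ndarray,
               boundary_mix: bool = True, iters: int = 48):
    """Vectorised boundary LRT over many columns with quality-binned counts.

    ``k``/``n`` are (columns, quality-levels) counts of the tested allele
    and of all covering bases; ``e_lv`` the per-level error probabilities.
    Golden-section search exploits concavity of the log-likelihood.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    e = np.asarray(e_lv, dtype=float)

    def ll(theta):
        p = (1.0 - e) * theta[:, None] + (e / 3.0) * (1.0 - theta[:, None])
        return np.sum(k * np.log(p) + (n - k) * np.log1p(-p), axis=1)

    m = k.shape[0]
    if m == 0:
        z = np.zeros(0)
        return z, z, np.ones(0)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.zeros(m)
    b = np.ones(m)
    for _ in range(iters):
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        upper = ll(c) < ll(d)
        a = np.where(upper, c, a)
        b = np.where(upper, b, d)
    theta = 0.5 * (a + b)
    ll0 = np.sum(k * np.log(e / 3.0) + (n - k) * np.log1p(-e / 3.0), axis=1)
    ll_hat = np.maximum(ll(theta), ll0)
    t = np.maximum(0.0, 2.0 * (ll_hat - ll0))
    none = k.sum(axis=1) == 0
    theta[none] = 0.0
    t[none] = 0.0
    p = np.where(t > 0.0, (0.5 if boundary_mix else 1.0) * chi2.sf(t, 1), 1.0)
    return theta, t, p


# ---------------------------------------------------------------------------
# PCR error model and consensus quality
# ---------------------------------------------------------------------------

def pcr_error_rate(per_cycle_error: float, cycles: int) -> float:
    """Coalescent PCR error rate: 1 - (1 - per-cycle error)^(2^m - 1)."""
    if cycles < 0:
        raise ValueError("negative cycle count")
    if not 0.0 <= per_cycle_error < 1.0:
        raise ValueError("per-cycle error outside [0, 1)")
    copies = 2.0 ** cycles - 1.0
    return float(-np.expm1(copies * np.log1p(-per_cycle_error)))


@dataclass(frozen=True)
class PcrModel:
    """Overall PCR error for a consensus base: P_pcr ~ n * e_pcr^2.

    ``n`` is the number of DNA templates behind the consensus; by default
    the caller uses the template (fragment) count of the read family the
    consensus was built from, with a "column" mode that instead counts
    consensus sequences covering the position.
    """

    cycles: int = 12
    per_cycle_error: float = 1e-6
    n_mode: str = "family"        # "family" or "column"

    @property
    def e_pcr(self) -> float:
        return pcr_error_rate(self.per_cycle_error, self.cycles)

    def p_pcr(self, n_templates: int) -> float:
        return float(n_templates) * self.e_pcr ** 2


def combined_quality(p_c: float, p_pcr: float) -> Tuple[int, str]:
    """Eq-7 consensus base quality: Q = -10 log10(P_c + P_pcr), Phred+33."""
    total = p_c + p_pcr
    if total <= 0.0 or total > 1.0:
        raise ValueError(f"error sum {total} outside (0, 1]")
    q = int(round(-10.0 * np.log10(total)))
    q = max(0, min(MAX_QUALITY, q))
    return q, chr(q + 33)


# ---------------------------------------------------------------------------
# Read families
# ---------------------------------------------------------------------------

@dataclass
class ReadFamily:
    """Reads treated as copies of one original template."""

    key: tuple
    reads: List[AlignedRead]
    n_fragments: int = 1


def build_read_families(reads: Iterable[AlignedRead],
                        contig: Optional[str] = None) -> List[ReadFamily]:
    """Group read pairs sharing both mates' positions and CIGAR strings.

    Duplicate-flagged reads are grouped like any other: template
    redundancy is the caller's signal, not noise.  Unpaired reads form
    singleton families.
    """
    pairs: Dict[str, List[AlignedRead]] = {}
    singles: List[AlignedRead] = []
    for read in reads:
        if read.is_secondary or read.is_supplementary:
            continue
        if contig is not None and read.contig != contig:
            continue
        if read.is_paired:
            pairs.setdefault(read.qname, []).append(read)
        else:
            singles.append(read)
    families: Dict[tuple, ReadFamily] = {}
    orphan = 0
    for qname in sorted(pairs):
        mates = sorted(pairs[qname], key=lambda r: r.pos)
        if len(mates) == 2:
            key = (mates[0].pos, mates[0].cigar, mates[1].pos, mates[1].cigar)
        else:
            key = ("orphan", orphan)
            orphan += 1
        fam = families.get(key)
        if fam is None:
            families[key] = ReadFamily(key, list(mates), 1)
        else:
            fam.reads.extend(mates)
            fam.n_fragments += 1
    out = list(families.values())
    for i, read in enumerate(singles):
        out.append(ReadFamily(("single", i), [read], 1))
    return out


# ---------------------------------------------------------------------------
# Consensus construction
# ---------------------------------------------------------------------------

@dataclass
class ConsensusSequence:
    """Template-level sequence with combined base qualities.

    ``bases`` uses code 4 ('N') at alleles rejected by round one.  A family
    holding discordant passing alleles splits into several consensus
    sequences, one per allele group.
    """

    family_key: tuple
    positions: np.ndarray         # (m,) 1-based reference positions
    bases: np.ndarray             # (m,) uint8 codes, 4 = 'N'
    errors: np.ndarray            # (m,) combined error P_c + P_pcr
    quals: np.ndarray             # (m,) uint8 encoded quality
    strands: np.ndarray           # (m,) uint8: 0 forward, 1 reverse
    n_members: int
    n_fragments: int
    indels: List[tuple] = field(default_factory=list)
    all_n: bool = False

    def base_string(self) -> str:
        return decode_seq(self.bases)

    def quality_string(self) -> str:
        return "".join(chr(q + 33) for q in self.quals)


def _member_evidence(read: AlignedRead, min_bq: int):
    pos, bases, quals, indels = read.aligned_bases()
    keep = quals > min_bq
    return (pos[keep], bases[keep], quals[keep],
            1 if read.is_reverse else 0, indels)


def build_consensus(family: ReadFamily, passed,
                    reference: CircularReference,
                    pcr: PcrModel = PcrModel(),
                    min_bq: int = MIN_BASE_QUALITY) -> List[ConsensusSequence]:
    """Collapse one read family into consensus sequence(s).

    ``passed`` is an (L, 4) boolean table of alleles retained by round one
    on both strands (or any object supporting ``passed[pos-1, code]``).
    Alleles that are neither reference nor retained become 'N'; members
    carrying discordant retained alleles split the family.
    """
    members = [_member_evidence(r, min_bq) for r in family.reads]
    members = [m for m in members if len(m[0])]
    if not members:
        return [ConsensusSequence(family.key, np.empty(0, dtype=int),
                                  np.empty(0, dtype=np.uint8),
                                  np.empty(0), np.empty(0, dtype=np.uint8),
                                  np.empty(0, dtype=np.uint8),
                                  len(family.reads), family.n_fragments,
                                  [], all_n=True)]
    ref_codes = reference.codes
    return _consensus_from_members(members, family, passed, ref_codes, pcr)


def _consensus_from_members(members, family: ReadFamily, passed,
                            ref_codes: np.ndarray,
                            pcr: PcrModel) -> List[ConsensusSequence]:
    allowed_members = []
    for pos, bases, quals, strand, indels in members:
        ref_here = ref_codes[pos - 1]
        ok = (bases == ref_here) | passed[pos - 1, np.minimum(bases, 3)]
        ok &= bases < 4
        masked = np.where(ok, bases, np.uint8(4))
        allowed_members.append((pos, masked, quals, strand, indels))

    # member x column matrices over the family's span (255 = uncovered)
    n = len(allowed_members)
    pmin = min(int(m[0].min()) for m in allowed_members)
    pmax = max(int(m[0].max()) for m in allowed_members)
    width = pmax - pmin + 1
    B = np.full((n, width), 255, dtype=np.uint8)
    Q = np.zeros((n, width), dtype=np.int16)
    S = np.zeros(n, dtype=np.uint8)
    for i, (pos, masked, quals, strand, _) in enumerate(allowed_members):
        B[i, pos - pmin] = masked
        Q[i, pos - pmin] = quals
        S[i] = strand

    cnt = np.stack([(B == a).sum(axis=0) for a in range(4)])
    if n == 1 or ((cnt > 0).sum(axis=0) <= 1).all():
        groups = [list(range(n))]
    else:
        # discordant retained alleles split the family into allele groups
        discordant = set((np.nonzero((cnt > 0).sum(axis=0) > 1)[0]
                          + pmin).tolist())
        groups = []
        signatures: List[Dict[int, int]] = []
        for mi, (pos, masked, _, _, _) in enumerate(allowed_members):
            sig = {int(p): int(b) for p, b in zip(pos, masked)
                   if int(p) in discordant and b < 4}
            placed = False
            for gi, gsig in enumerate(signatures):
                if all(gsig.get(p, b) == b for p, b in sig.items()):
                    groups[gi].append(mi)
                    gsig.update(sig)
                    placed = True
                    break
            if not placed:
                groups.append([mi])
                signatures.append(dict(sig))

    out = []
    for group in groups:
        out.append(_matrix_consensus(
            B[group], Q[group], S[group],
            [allowed_members[i][4] for i in group], pmin, family, pcr))
    return out


def _matrix_consensus(B: np.ndarray, Q: np.ndarray, S: np.ndarray,
                      indel_lists, pmin: int, family: ReadFamily,
                      pcr: PcrModel) -> ConsensusSequence:
    """Majority-vote consensus of one allele group, fully vectorised.

    Ties resolve by summed quality, then by base order; the combined error
    multiplies the supporting members' error probabilities (coalescing at
    the 3-way substitution alternatives) and adds the PCR term.
    """
    n, width = B.shape
    n_frag = max(1, min(family.n_fragments, (n + 1) // 2))
    p_pcr = pcr.p_pcr(n_frag if pcr.n_mode == "family" else 1)
    cols = np.arange(width)
    cnt = np.stack([(B == a).sum(axis=0) for a in range(4)])
    qsum = np.stack([np.where(B == a, Q, 0).sum(axis=0) for a in range(4)])
    score = (cnt.astype(np.int64) * 1_000_000 + qsum) * 4 \
        + (3 - np.arange(4))[:, None]
    score[cnt == 0] = -1
    best = score.argmax(axis=0)
    sup = cnt[best, cols]
    has_base = sup > 0
    covered = B.min(axis=0) < 255

    log_e = np.maximum(-(Q.astype(np.float64)) / 10.0, np.log10(ERROR_FLOOR))
    log_pc = np.stack([np.where(B == a, log_e, 0.0).sum(axis=0)
                       for a in range(4)])[best, cols] \
        + (1 - sup) * np.log10(3.0)
    total = np.minimum(np.power(10.0, log_pc) + p_pcr, 0.999999)
    qv = np.clip(np.round(-10.0 * np.log10(total)), 0,
                 MAX_QUALITY).astype(np.uint8)
    fwd = np.stack([((B == a) & (S[:, None] == 0)).sum(axis=0)
                    for a in range(4)])[best, cols] > 0
    fallback_strand = S[(B < 255).argmax(axis=0)]

    idx = np.nonzero(covered)[0]
    bases = np.where(has_base, best, 4).astype(np.uint8)[idx]
    errors = np.where(has_base, total, 0.75)[idx]
    quals = np.where(has_base, qv, 0).astype(np.uint8)[idx]
    strands = np.where(has_base, np.where(fwd, 0, 1),
                       fallback_strand).astype(np.uint8)[idx]

    # indel marks: carried when a majority of anchor-covering members agree
    indel_votes: Dict[tuple, int] = {}
    for indels in indel_lists:
        for anchor, kind, alt in indels:
            indel_votes[(anchor, kind, alt)] = \
                indel_votes.get((anchor, kind, alt), 0) + 1
    member_cov = (B < 255).sum(axis=0)
    indels_out = []
    for (anchor, kind, alt), votes in sorted(indel_votes.items()):
        col = anchor - pmin
        covering = int(member_cov[col]) if 0 <= col < width else n
        if 2 * votes >= max(1, covering):
            indels_out.append((anchor, kind, alt))

    return ConsensusSequence(
        family_key=family.key, positions=pmin + idx, bases=bases,
        errors=errors, quals=quals, strands=strands,
        n_members=n, n_fragments=family.n_fragments,
        indels=indels_out, all_n=bool((bases == 4).all()))


# ---------------------------------------------------------------------------
# Round two over consensus sequences
# ---------------------------------------------------------------------------

def _counts_from_consensi(consensi: Sequence[ConsensusSequence], length: int,
                          min_bq: int):
    counts = np.zeros((length, 5, QMAX, 2), dtype=np.int32)
    denom = np.zeros(length, dtype=np.int64)
    indel_support: Dict[tuple, int] = {}
    for cons in consensi:
        keep = cons.quals > min_bq
        keep |= cons.bases == 4      # 'N' still occupies the template slot
        pos = cons.positions[keep] - 1
        b = cons.bases[keep]
        q = np.minimum(cons.quals[keep], QMAX - 1)
        s = cons.strands[keep]
        np.add.at(counts, (pos, b, q, s), 1)
        np.add.at(denom, pos, 1)
        for anchor, kind, alt in cons.indels:
            key = (anchor, kind, alt)
            indel_support[key] = indel_support.get(key, 0) + 1
    return counts, denom, indel_support


def _snv_calls_from_counts(counts: np.ndarray, denom: np.ndarray,
                           reference: CircularReference, alpha: float,
                           min_bq: int, boundary_mix: bool,
                           require_both_strands: bool,
                           source: str = "round2") -> List[VariantCall]:
    length = reference.length
    ref_codes = reference.codes
    q_lo = min_bq + 1
    cq = counts[:, :4, q_lo:, :]
    e_lv = np.maximum(phred_to_error(np.arange(q_lo, QMAX), floor=0.0), 1e-10)
    cov = cq.sum(axis=1)                            # informative bases only
    present = cq.sum(axis=2) > 0                    # (L, 4, 2)
    is_alt = np.ones((length, 4), dtype=bool)
    valid_ref = ref_codes < 4
    is_alt[np.arange(length)[valid_ref], ref_codes[valid_ref]] = False
    cand = is_alt & present[..., 0] & present[..., 1] if require_both_strands \
        else is_alt & (present[..., 0] | present[..., 1])
    pos_idx, allele_idx = np.nonzero(cand)
    if len(pos_idx) == 0:
        return []
    p_strand = []
    for s in (0, 1):
        _, _, p = _batch_lrt(cq[pos_idx, allele_idx, :, s],
                             cov[pos_idx, :, s], e_lv, boundary_mix)
        p_strand.append(p)
    p_f, p_r = p_strand
    passed = (p_f <= alpha) & (p_r <= alpha) if require_both_strands \
        else (np.minimum(p_f, p_r) <= alpha)
    calls = []
    for j in np.nonzero(passed)[0]:
        pos = int(pos_idx[j]) + 1
        alt_code = int(allele_idx[j])
        kf = int(cq[pos - 1, alt_code, :, 0].sum())
        kr = int(cq[pos - 1, alt_code, :, 1].sum())
        dp = int(denom[pos - 1])
        calls.append(VariantCall(
            contig=reference.name, pos=pos,
            ref=reference.base(pos), alt="ACGT"[alt_code], vtype=SNV,
            vaf=(kf + kr) / dp if dp else 0.0,
            depth=dp, fwd_support=kf, rev_support=kr,
            p_value=float(max(p_f[j], p_r[j])), source=source))
    return calls


def lrt_consensus(consensi: Sequence[ConsensusSequence],
                  reference: CircularReference, alpha: float = ALPHA,
                  min_bq: int = MIN_BASE_QUALITY, boundary_mix: bool = True,
                  require_both_strands: bool = True) -> List[VariantCall]:
    """Round-two likelihood tests over consensus sequences (SNVs)."""
    counts, denom, _ = _counts_from_consensi(consensi, reference.length,
                                             min_bq)
    return _snv_calls_from_counts(counts, denom, reference, alpha, min_bq,
                                  boundary_mix, require_both_strands)


@dataclass(frozen=True)
class IndelSelection:
    position: int
    kind: str                     # INS / DEL
    alt: object                   # inserted bases or deletion length
    support: int


def select_indel(position: int,
                 consensi: Sequence[ConsensusSequence]
                 ) -> Optional[IndelSelection]:
    """Pick the indel allele with maximum consensus support at a position.

    Ties break on the VCF-style (ref, alt) allele strings, smallest first,
    so results are deterministic across runs.
    """
    support: Dict[tuple, int] = {}
    for cons in consensi:
        for anchor, kind, alt in cons.indels:
            if anchor == position:
                support[(kind, alt)] = support.get((kind, alt), 0) + 1
    if not support:
        return None
    def sort_key(item):
        (kind, alt), count = item
        alt_str = alt if kind == INS else "-" * int(alt)
        return (-count, str(alt_str), kind)
    (kind, alt), count = sorted(support.items(), key=sort_key)[0]
    return IndelSelection(position, kind, alt, count)


def _indel_calls(indel_support: Dict[tuple, int], denom: np.ndarray,
                 reference: CircularReference, min_support: int,
                 source: str = "round2") -> List[VariantCall]:
    best: Dict[int, tuple] = {}
    for (anchor, kind, alt), count in indel_support.items():
        if count < min_support:
            continue
        anchor = int(anchor)
        if anchor < 1 or anchor > reference.length:
            continue
        alt_str = alt if kind == INS else "-" * int(alt)
        entry = (count, str(alt_str), kind, alt)
        current = best.get(anchor)
        if current is None or (-entry[0], entry[1]) < (-current[0], current[1]):
            best[anchor] = entry
    calls = []
    for anchor, (count, _, kind, alt) in sorted(best.items()):
        anchor_base = reference.base(anchor)
        if kind == INS:
            ref_allele = anchor_base
            alt_allele = anchor_base + str(alt)
            vtype = INS
        else:
            length = int(alt)
            if anchor + length > reference.length:
                continue
            ref_allele = anchor_base + reference.sequence[anchor:anchor + length]
            alt_allele = anchor_base
            vtype = DEL
        dp = int(denom[anchor - 1])
        calls.append(VariantCall(
            contig=reference.name, pos=anchor, ref=ref_allele,
            alt=alt_allele, vtype=vtype,
            vaf=count / dp if dp else 0.0, depth=dp,
            fwd_support=count, rev_support=count,
            indel_support=count, source=source))
    return calls


# ---------------------------------------------------------------------------
# Callset merging
# ---------------------------------------------------------------------------

def merge_callsets(low_vaf: Sequence[VariantCall],
                   high_vaf: Sequence[VariantCall],
                   cutoff: float = 0.01,
                   low_floor: float = 0.001) -> List[VariantCall]:
    """Integrate a low-VAF callset with a conventional high-VAF callset.

    Low-VAF calls are kept for VAF in [``low_floor``, ``cutoff``]; high-VAF
    calls for VAF > ``cutoff``.  Where both sets report the same locus the
    high-VAF record wins.
    """
    kept_high = [c for c in high_vaf if c.vaf > cutoff]
    high_pos = {}
    for call in kept_high:
        high_pos.setdefault((call.contig, call.pos), []).append(call)
    out = list(kept_high)
    for call in low_vaf:
        if not low_floor <= call.vaf <= cutoff:
            continue
        clash = high_pos.get((call.contig, call.pos))
        if clash:
            for other in clash:
                if other.vtype == SNV and call.vtype == SNV \
                        and other.ref != call.ref:
                    raise ValueError(
                        f"conflicting reference alleles at {call.pos}")
            continue
        out.append(call)
    return sorted(out, key=lambda c: (c.contig, c.pos, c.alt))


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def _accumulate_block_counts(counts: np.ndarray, block: ReadBlock,
                             idx: np.ndarray, min_bq: int,
                             chunk: int = 50_000):
    """Round-one pileup for simple (all-matching) reads, chunked bincount."""
    length = counts.shape[0]
    rl = block.read_len
    offsets = np.arange(rl)
    flat_size = counts.size
    for lo in range(0, len(idx), chunk):
        rows = idx[lo:lo + chunk]
        pos = block.pos[rows][:, None] + offsets[None, :]
        base = block.seq[rows]
        qual = np.minimum(block.qual[rows], QMAX - 1)
        strand = np.broadcast_to(block.strand[rows][:, None], pos.shape)
        ok = (base < 4) & (qual > min_bq)
        flat = ((pos * 4 + base).astype(np.int64) * QMAX + qual) * 2 + strand
        add = np.bincount(flat[ok].ravel(), minlength=flat_size)
        counts.ravel()[:] += add.astype(counts.dtype)


def _round_one(counts: np.ndarray, reference: CircularReference,
               alpha: float, min_bq: int, boundary_mix: bool,
               e_floor: float = ERROR_FLOOR):
    """Per-strand LRTs for every candidate alternative allele.

    Returns the (L, 4) table of alleles passing on both strands.
    """
    length = reference.length
    ref_codes = reference.codes
    q_lo = min_bq + 1
    cq = counts[:, :, q_lo:, :]
    e_lv = phred_to_error(np.arange(q_lo, QMAX), floor=e_floor)
    cov = cq.sum(axis=1)
    present = cq.sum(axis=2) > 0
    is_alt = np.ones((length, 4), dtype=bool)
    valid_ref = ref_codes < 4
    is_alt[np.arange(length)[valid_ref], ref_codes[valid_ref]] = False
    cand = is_alt & present[..., 0] & present[..., 1]
    passed = np.zeros((length, 4), dtype=bool)
    pos_idx, allele_idx = np.nonzero(cand)
    if len(pos_idx) == 0:
        return passed
    ok = np.ones(len(pos_idx), dtype=bool)
    for s in (0, 1):
        _, _, p = _batch_lrt(cq[pos_idx, allele_idx, :, s],
                             cov[pos_idx, :, s], e_lv, boundary_mix)
        ok &= p <= alpha
    passed[pos_idx[ok], allele_idx[ok]] = True
    return passed


def _q2_lookup(pcr: PcrModel) -> np.ndarray:
    """Singleton-template consensus quality per input quality."""
    e_in = phred_to_error(np.arange(QMAX))
    p_pcr = pcr.p_pcr(1)
    q2 = np.round(-10.0 * np.log10(e_in + p_pcr)).astype(int)
    return np.clip(q2, 0, QMAX - 1).astype(np.uint8)


def _consensus_fast(counts2, denom, block: ReadBlock, rows: np.ndarray,
                    allowed: np.ndarray, q2_lut: np.ndarray, min_bq: int,
                    chunk: int = 50_000):
    """Consensus pileup for singleton-family, all-matching, non-overlapping
    fragments: each read base is its own consensus observation."""
    rl = block.read_len
    offsets = np.arange(rl)
    flat_size = counts2.size
    for lo in range(0, len(rows), chunk):
        rr = rows[lo:lo + chunk]
        pos = block.pos[rr][:, None] + offsets[None, :]
        base = block.seq[rr]
        qual = np.minimum(block.qual[rr], QMAX - 1)
        strand = np.broadcast_to(block.strand[rr][:, None], pos.shape)
        admit = (base < 4) & (qual > min_bq)
        keep = allowed[pos, np.minimum(base, 3)] & admit
        out_base = np.where(keep, base, np.uint8(4))
        q2 = q2_lut[qual]
        flat = ((pos * 5 + out_base).astype(np.int64) * QMAX + q2) * 2 + strand
        add = np.bincount(flat[admit].ravel(), minlength=flat_size)
        counts2.ravel()[:] += add.astype(counts2.dtype)
        np.add.at(denom, pos[admit].ravel(), 1)


def call_variants(reads: Union[ReadBlock, Iterable[AlignedRead]],
                  reference: CircularReference, *,
                  alpha: float = ALPHA,
                  min_bq: int = MIN_BASE_QUALITY,
                  min_mq: int = MIN_MAPPING_QUALITY,
                  pcr: PcrModel = PcrModel(),
                  min_indel_support: int = 2,
                  boundary_mix: bool = True,
                  require_both_strands: bool = True,
                  blacklist: Optional[Blacklist] = None) -> List[VariantCall]:
    """Run the full two-round caller and return confident variants.

    Accepts either the compact :class:`ReadBlock` (deep simulated pileups)
    or any iterable of :class:`AlignedRead`.  Blacklisted positions are
    called but flagged, never suppressed.
    """
    if blacklist is None:
        blacklist = Blacklist.default_mt() \
            if reference.length == 16569 else Blacklist()
    if isinstance(reads, ReadBlock):
        calls = _call_block(reads, reference, alpha, min_bq, min_mq, pcr,
                            min_indel_support, boundary_mix,
                            require_both_strands)
    else:
        calls = _call_read_list(list(reads), reference, alpha, min_bq,
                                min_mq, pcr, min_indel_support, boundary_mix,
                                require_both_strands)
    for call in calls:
        if blacklist.contains(call.pos):
            call.filter = "blacklist"
    return sorted(calls, key=lambda c: (c.pos, c.alt))


def _call_block(block: ReadBlock, reference: CircularReference,
                alpha, min_bq, min_mq, pcr, min_indel_support,
                boundary_mix, require_both_strands) -> List[VariantCall]:
    length = reference.length
    mq_ok = block.mapq > min_mq
    simple = (block.cigar_id == 0) & mq_ok
    complex_rows = np.nonzero(~simple & mq_ok)[0]
    simple_rows = np.nonzero(simple)[0]

    counts1 = np.zeros((length, 4, QMAX, 2), dtype=np.int32)
    _accumulate_block_counts(counts1, block, simple_rows, min_bq)
    complex_cache = {}
    for i in complex_rows:
        read = _block_read(block, int(i))
        pos, bases, quals, indels = read.aligned_bases()
        complex_cache[int(i)] = (pos, bases, quals, indels,
                                 int(block.strand[i]))
        keep = (bases < 4) & (quals > min_bq) & (pos >= 1) & (pos <= length)
        np.add.at(counts1,
                  (pos[keep] - 1, bases[keep],
                   np.minimum(quals[keep], QMAX - 1),
                   np.full(keep.sum(), block.strand[i], dtype=np.int64)), 1)

    passed = _round_one(counts1, reference, alpha, min_bq, boundary_mix)
    allowed = passed.copy()
    ref_codes = reference.codes
    valid_ref = ref_codes < 4
    allowed[np.arange(length)[valid_ref], ref_codes[valid_ref]] = True

    # family structure over fragments
    frag_ids, fam_of_frag, n_fam = block.family_keys()
    frag_index = {int(f): i for i, f in enumerate(frag_ids)}
    fam_sizes = np.bincount(fam_of_frag, minlength=n_fam)
    read_frag_slot = np.array([frag_index[int(f)] for f in block.frag_id])
    read_fam = fam_of_frag[read_frag_slot]

    frag_complex = np.zeros(len(frag_ids), dtype=bool)
    frag_complex[read_frag_slot[~simple]] = True
    # mate overlap per fragment
    order = np.lexsort((block.pos, block.frag_id))
    p1 = block.pos[order[0::2]]
    p2 = block.pos[order[1::2]]
    frag_sorted_ids = block.frag_id[order[0::2]]
    overlap_by_frag = np.zeros(len(frag_ids), dtype=bool)
    slots = np.array([frag_index[int(f)] for f in frag_sorted_ids])
    overlap_by_frag[slots] = (p2 - p1) < block.read_len
    frag_mq_bad = np.zeros(len(frag_ids), dtype=bool)
    frag_mq_bad[read_frag_slot[~mq_ok]] = True

    special_fam = np.zeros(n_fam, dtype=bool)
    special_fam |= fam_sizes > 1
    special_fam[fam_of_frag[frag_complex]] = True
    special_fam[fam_of_frag[overlap_by_frag]] = True
    read_special = special_fam[read_fam] | ~mq_ok

    counts2 = np.zeros((length, 5, QMAX, 2), dtype=np.int32)
    denom = np.zeros(length, dtype=np.int64)
    q2_lut = _q2_lookup(pcr)
    fast_rows = np.nonzero(~read_special)[0]
    _consensus_fast(counts2, denom, block, fast_rows, allowed, q2_lut, min_bq)

    # remaining families go through the general consensus machinery
    indel_support: Dict[tuple, int] = {}
    special_rows = np.nonzero(read_special & mq_ok)[0]
    if len(special_rows):
        by_fam: Dict[int, list] = {}
        for i in special_rows:
            by_fam.setdefault(int(read_fam[i]), []).append(int(i))
        rl_offsets = np.arange(block.read_len)
        for fam_id, row_list in sorted(by_fam.items()):
            members = []
            for i in row_list:
                if i in complex_cache:
                    pos, bases, quals, indels, strand = complex_cache[i]
                    keep = quals > min_bq
                    members.append((pos[keep], bases[keep], quals[keep],
                                    strand, indels))
                else:
                    pos = int(block.pos[i]) + 1 + rl_offsets
                    bases = block.seq[i]
                    quals = block.qual[i]
                    keep = quals > min_bq
                    members.append((pos[keep], bases[keep],
                                    quals[keep].astype(np.int16),
                                    int(block.strand[i]), []))
            members = [m for m in members if len(m[0])]
            if not members:
                continue
            fam = ReadFamily(("block", fam_id), [],
                             n_fragments=int(fam_sizes[fam_id]))
            for cons in _consensus_from_members(members, fam, allowed,
                                                ref_codes, pcr):
                keep = cons.positions <= length
                pos0 = cons.positions[keep] - 1
                np.add.at(counts2,
                          (pos0, cons.bases[keep],
                           np.minimum(cons.quals[keep], QMAX - 1),
                           cons.strands[keep].astype(np.int64)), 1)
                np.add.at(denom, pos0, 1)
                for anchor, kind, alt in cons.indels:
                    key = (anchor, kind, alt)
                    indel_support[key] = indel_support.get(key, 0) + 1

    calls = _snv_calls_from_counts(counts2, denom, reference, alpha, min_bq,
                                   boundary_mix, require_both_strands)
    calls += _indel_calls(indel_support, denom, reference, min_indel_support)
    return calls


def _block_read(block: ReadBlock, i: int) -> AlignedRead:
    return AlignedRead(
        qname=f"frag{block.frag_id[i]}", contig=block.contig,
        pos=int(block.pos[i]) + 1, mapq=int(block.mapq[i]),
        cigar=block.cigars[block.cigar_id[i]],
        seq=decode_seq(block.seq[i]), qual=block.qual[i].copy(),
        is_reverse=bool(block.strand[i]))


def _call_read_list(reads: List[AlignedRead], reference: CircularReference,
                    alpha, min_bq, min_mq, pcr, min_indel_support,
                    boundary_mix, require_both_strands) -> List[VariantCall]:
    length = reference.length
    usable = [r for r in reads
              if not r.is_secondary and not r.is_supplementary
              and r.contig == reference.name and r.mapq > min_mq]
    counts1 = np.zeros((length, 4, QMAX, 2), dtype=np.int32)
    for read in usable:
        pos, bases, quals, _ = read.aligned_bases()
        keep = (bases < 4) & (quals > min_bq) & (pos >= 1) & (pos <= length)
        np.add.at(counts1,
                  (pos[keep] - 1, bases[keep],
                   np.minimum(quals[keep], QMAX - 1),
                   np.full(int(keep.sum()), 1 if read.is_reverse else 0,
                           dtype=np.int64)), 1)
    passed = _round_one(counts1, reference, alpha, min_bq, boundary_mix)
    allowed = passed.copy()
    ref_codes = reference.codes
    valid_ref = ref_codes < 4
    allowed[np.arange(length)[valid_ref], ref_codes[valid_ref]] = True

    families = build_read_families(usable, contig=reference.name)
    consensi = []
    for fam in families:
        consensi.extend(build_consensus(fam, allowed, reference, pcr, min_bq))
    counts2, denom, indel_support = _counts_from_consensi(
        consensi, length, min_bq)
    calls = _snv_calls_from_counts(counts2, denom, reference, alpha, min_bq,
                                   boundary_mix, require_both_strands)
    calls += _indel_calls(indel_support, denom, reference, min_indel_support)
    return calls
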