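"""Benchmark harness: simulate -> call -> score at desk scale.

Reproduces the simulation-grid evaluation design (seven VAFs x three
depths, one shared 30-variant panel per replicate) and a NUMT fixture
benchmark measuring detection recall and breakpoint distances, including
origin-spanning segments and planted mismatches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .dmtlv import call_variants
from . import fnumt
from .reference import CircularReference, circular_position
from .simulate import (
    PAPER_DEPTHS, PAPER_VAFS, NumtSimConfig, TruthLedger, VariantSimConfig,
    plant_numt, plant_variants, score_calls, simulate_reads,
)


@dataclass
class RunConfig:
    """Serializable record of a run; re-running from it reproduces outputs."""

    command: str
    seed: int
    parameters: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def _cell_seed(seed: int, index: int) -> int:
    return (seed * 1_000_003 + 7919 * (index + 1)) % (2**31 - 1)


def lrt_null_calibration(n_columns: int = 100_000, depth: int = 20_000,
                         qualities: Sequence[int] = tuple(range(13, 24)),
                         alphas: Sequence[float] = (1e-2, 1e-3),
                         seed: int = 0, boundary_mix: bool = True,
                         chunk: int = 100_000) -> dict:
    """Monte-Carlo null calibration of the boundary likelihood-ratio test.

    Columns of ``depth`` reads are generated purely from the sequencing
    error model: each read carries an integer Phred quality drawn
    uniformly from ``qualities`` (the raw pre-filter Illumina range) and
    shows the tested allele with probability e/3.  The empirical
    rejection rate at each level should match the nominal level when the
    expected error count per column is large; see the methods note for
    the regime of validity.
    """
    from .dmtlv import _batch_lrt, phred_to_error
    e_levels = phred_to_error(np.asarray(qualities), floor=0.0)
    rng = np.random.default_rng(_cell_seed(seed, 97))
    weights = np.full(len(e_levels), 1.0 / len(e_levels))
    rejections = {alpha: 0 for alpha in alphas}
    t_zero = 0
    for lo in range(0, n_columns, chunk):
        m = min(chunk, n_columns - lo)
        n_q = rng.multinomial(depth, weights, size=m)
        k_q = rng.binomial(n_q, e_levels / 3.0)
        _, t, p = _batch_lrt(k_q, n_q, e_levels, boundary_mix)
        t_zero += int((t == 0).sum())
        for alpha in alphas:
            rejections[alpha] += int((p <= alpha).sum())
    out = {"n_columns": n_columns, "depth": depth,
           "p_t_zero": t_zero / n_columns}
    for alpha in alphas:
        out[alpha] = rejections[alpha] / n_columns
    return out


def run_benchmark_grid(reference: Optional[CircularReference] = None,
                       vafs: Sequence[float] = PAPER_VAFS,
                       depths: Sequence[float] = PAPER_DEPTHS,
                       reps: int = 1, seed: int = 0,
                       config: Optional[VariantSimConfig] = None,
                       call_kwargs: Optional[dict] = None) -> pd.DataFrame:
    """Simulate, call and score every (VAF, depth) grid cell.

    One variant panel is planted per replicate and shared across the
    grid; read sets differ per cell.  Per-cell failures are recorded in
    the ``error`` column and the grid continues.
    """
    if reference is None:
        reference = CircularReference.random_mt(seed=4242)
    base = config or VariantSimConfig()
    call_kwargs = call_kwargs or {}
    rows = []
    for rep in range(reps):
        rep_seed = _cell_seed(seed, rep)
        template, wild, panel = plant_variants(reference, base,
                                               seed=rep_seed)
        for ci, (vaf, depth) in enumerate(
                (v, d) for d in depths for v in vafs):
            cell = {"vaf": vaf, "depth": depth, "rep": rep,
                    "seed": _cell_seed(rep_seed, ci), "error": ""}
            try:
                cfg = replace(base, vaf=vaf, depth=depth)
                block = simulate_reads(template, wild, cfg,
                                       seed=cell["seed"],
                                       contig=reference.name)
                calls = call_variants(block, reference, **call_kwargs)
                ledger = TruthLedger(variants=[replace(v, vaf=vaf)
                                               for v in panel.variants])
                metrics = score_calls(calls, ledger)
                for vtype in ("SNV", "INS", "DEL"):
                    for stat in ("tpr", "ppv", "f1"):
                        cell[f"{vtype.lower()}_{stat}"] = \
                            metrics[vtype][stat]
                cell["pearson_r"] = metrics["pearson_r"]
                cell["n_calls"] = len(calls)
                cell["pairs"] = metrics["pairs"]
            except Exception as exc:   # grid continues past cell failures
                cell["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(cell)
    return pd.DataFrame(rows)


def default_numt_configs(n_fixtures: int = 20, n_origin_spanning: int = 5,
                         n_with_mismatches: int = 5, error_rate: float = 0.0,
                         depth: float = 30.0, seed: int = 0,
                         mt_length: int = 16569) -> List[NumtSimConfig]:
    """Seeded fixture grid: segment sizes 300-700 bp, alternating
    zygosity, the first fixtures spanning the circular origin and a
    following group carrying planted mismatches."""
    rng = np.random.default_rng(seed)
    configs = []
    for i in range(n_fixtures):
        size = int(rng.integers(300, 701))
        if i < n_origin_spanning:
            mt_end = int(rng.integers(40, size - 40))
            mt_start = circular_position(mt_end - size, mt_length)
        else:
            mt_start = int(rng.integers(100, mt_length - size - 100))
            mt_end = mt_start + size
        n_mism = 3 if (n_origin_spanning <= i
                       < n_origin_spanning + n_with_mismatches) else 0
        configs.append(NumtSimConfig(
            mt_start=mt_start, mt_end=mt_end,
            zygosity="het" if i % 2 else "hom",
            n_mismatches=n_mism, depth=depth, error_rate=error_rate))
    return configs


def run_numt_benchmark(mt_ref: Optional[CircularReference] = None,
                       configs: Optional[Sequence[NumtSimConfig]] = None,
                       seed: int = 0, depth: float = 30.0,
                       error_rate: float = 0.0):
    """Plant, detect and score a set of NUMT fixtures.

    Returns ``(per-fixture DataFrame, summary dict)``; the summary holds
    detection recall, breakpoint-distance statistics on the circular
    metric, false-call and mismatch-recovery counts.
    """
    if mt_ref is None:
        mt_ref = CircularReference.random_mt(seed=4242)
    if configs is None:
        configs = default_numt_configs(seed=seed, depth=depth,
                                       error_rate=error_rate,
                                       mt_length=mt_ref.length)
    rows = []
    all_dists: List[int] = []
    n_false = 0
    mism_expected = 0
    mism_found = 0
    for i, cfg in enumerate(configs):
        fx_seed = _cell_seed(seed, 1000 + i)
        reads, nuclear, truth = plant_numt(mt_ref, cfg, seed=fx_seed)
        calls, fps = fnumt.call_numts(
            reads, mt_ref, {nuclear.name: nuclear},
            mean_autosomal_coverage=cfg.depth, read_len=cfg.read_len)
        matched = None
        for call in calls:
            if (call.nuclear_contig == truth.nuclear_name
                    and abs(call.bp_left - truth.bp_left) <= 200):
                matched = call
            else:
                n_false += 1
        dists = (fnumt.breakpoint_distance(matched, truth, mt_ref.length)
                 if matched else [])
        all_dists.extend(dists)
        truth_mism = {(p, obs) for p, _, obs in truth.mismatches}
        found_mism = {(f.mt_pos, f.obs) for f in fps}
        mism_expected += len(truth_mism)
        mism_found += len(truth_mism & found_mism)
        rows.append({
            "fixture": i, "seed": fx_seed,
            "mt_start": truth.mt_start, "mt_end": truth.mt_end,
            "segment_size": truth.segment_size,
            "origin_spanning": truth.mt_start > truth.mt_end,
            "zygosity": truth.zygosity,
            "n_mismatches": len(truth.mismatches),
            "detected": matched is not None,
            "n_calls": len(calls),
            "max_distance": max(dists) if dists else np.nan,
            "mean_distance": float(np.mean(dists)) if dists else np.nan,
            "mismatches_recovered": len(truth_mism & found_mism),
            "called_zygosity": matched.zygosity if matched else "",
        })
    df = pd.DataFrame(rows)
    summary = {
        "recall": float(df["detected"].mean()) if len(df) else np.nan,
        "n_false_calls": int(n_false),
        "mean_breakpoint_distance": (float(np.mean(all_dists))
                                     if all_dists else np.nan),
        "max_breakpoint_distance": (int(np.max(all_dists))
                                    if all_dists else np.nan),
        "mismatch_recall": (mism_found / mism_expected
                            if mism_expected else np.nan),
        "n_mismatches_expected": mism_expected,
        "n_mismatches_found": mism_found,
    }
    return df, summary
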