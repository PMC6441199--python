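"""Benchmark metrics and the replicated study runner.

Metrics follow the standard DE-benchmark definitions: the false discovery
number (#{truly non-DE genes with p < cutoff}), precision (TP / predicted
positives), sensitivity (TP / real positives) and the F-score (harmonic
mean).  Rejection is strict ``p < cutoff`` throughout.  For real data,
where truth is unknown, an assumed-null FDR is computed against a set of
conserved orthologs taken to be non-DE.  Adjusted M/A values visualise
where a scaling factor sits relative to the non-DE cloud.

``run_study`` executes a named study design end to end per replicate:
simulate, estimate the scaling factor by each method, test all orthologs,
score.  Unique genes (expressed in one species only) are excluded from the
precision/sensitivity/false-discovery accounting: they are trivially
detected structural differences, not part of the DE-detection benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exact_test import test_all
from .io import ConservedSet, OrthologTable, filter_transcripts, read_conserved_list, read_ortholog_table
from .normalization import MedianNormalizer, SCBNNormalizer
from .simulation import SimConfig, StudyDesign, simulate_dataset, study_configs

__all__ = [
    "MetricRow",
    "false_discovery_number",
    "prf_metrics",
    "assumed_null_fdr",
    "ma_values",
    "run_study",
    "summarize_study",
    "real_data_summary",
]


@dataclass
class MetricRow:
    """One method x replicate x cutoff evaluation.

    ``precision`` and ``fscore`` are NaN ("missing") when undefined — zero
    predicted positives must not silently average as 0.
    """

    method: str
    replicate: int
    cutoff: float
    fd_number: int
    precision: float
    sensitivity: float
    fscore: float


def _check_lengths(pvalues, de_mask):
    p = np.asarray(pvalues, dtype=float)
    d = np.asarray(de_mask, dtype=bool)
    if p.shape != d.shape:
        raise ValueError("pvalues and de_mask must have equal length")
    return p, d


def false_discovery_number(pvalues, de_mask, cutoff: float) -> int:
    """#{genes with p < cutoff and de_mask false}."""
    p, d = _check_lengths(pvalues, de_mask)
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must lie in (0, 1)")
    return int(np.sum((p < cutoff) & ~d))


def prf_metrics(
    pvalues, de_mask, cutoff: float, method: str = "", replicate: int = 0
) -> MetricRow:
    """Precision, sensitivity and F-score at a p-value cutoff."""
    p, d = _check_lengths(pvalues, de_mask)
    if not d.any():
        raise ValueError("no true DE genes; precision/sensitivity undefined")
    reject = p < cutoff
    tp = int(np.sum(reject & d))
    fp = int(np.sum(reject & ~d))
    fn = int(np.sum(~reject & d))
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    sensitivity = tp / (tp + fn)
    if np.isnan(precision) or (precision + sensitivity) == 0:
        fscore = float("nan")
    else:
        fscore = 2 * precision * sensitivity / (precision + sensitivity)
    return MetricRow(
        method=method,
        replicate=replicate,
        cutoff=cutoff,
        fd_number=fp,
        precision=precision,
        sensitivity=sensitivity,
        fscore=fscore,
    )


def assumed_null_fdr(
    pvalues, conserved: ConservedSet, table: OrthologTable, cutoff: float
) -> float:
    """FDR proxy for real data: DE calls inside an assumed-non-DE conserved
    set, as a fraction of all DE calls."""
    p = np.asarray(pvalues, dtype=float)
    if p.shape[0] != len(table):
        raise ValueError("pvalues must align with the table rows")
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must lie in (0, 1)")
    calls = p < cutoff
    total = int(calls.sum())
    if total == 0:
        raise ValueError("no DE calls at this cutoff; FDR undefined")
    in_set = table.gene_ids.isin(set(conserved.ids)).to_numpy()
    return float(np.sum(calls & in_set) / total)


def ma_values(table: OrthologTable, c: float) -> pd.DataFrame:
    """Adjusted M/A values per gene with both counts positive.

    M = log2 of the ratio of length- and depth-adjusted expressions,
    A = mean log2 adjusted expression; the normalization line sits at
    M = log2(c).  Zero-count genes are excluded; the exclusion count is
    recorded in ``result.attrs["n_excluded"]``.
    """
    df = table.data
    N1, N2 = table.n1, table.n2
    pos = (df["x1"] > 0) & (df["x2"] > 0)
    sub = df.loc[pos]
    e1 = sub["x1"].to_numpy(float) / (sub["L1"].to_numpy(float) * N1)
    e2 = sub["x2"].to_numpy(float) / (sub["L2"].to_numpy(float) * N2)
    out = pd.DataFrame(
        {
            "gene_id": sub["gene_id"].to_numpy(),
            "A": 0.5 * np.log2(e1 * e2),
            "M": np.log2(e1 / e2),
        }
    )
    out.attrs["n_excluded"] = int((~pos).sum())
    out.attrs["m_line"] = float(np.log2(c))
    return out


def _fit_factor(method: str, table, conserved, alpha: float) -> float:
    if method == "scbn":
        return SCBNNormalizer(alpha=alpha).fit(table, conserved).scaling_factor_
    if method == "median":
        return MedianNormalizer().fit(table, conserved).scaling_factor_
    if method == "true":
        raise ValueError("'true' factor is resolved by the caller")
    raise ValueError(f"unknown normalization method {method!r}")


def run_study(
    study: str | StudyDesign,
    methods: Sequence[str] = ("scbn", "median"),
    reps: int = 100,
    cutoff: float | None = None,
    alpha: float = 0.05,
    seed: int | None = None,
    sweep_values: Iterable | None = None,
    config_overrides: dict | None = None,
) -> pd.DataFrame:
    """Run a named study design: one row per sweep value x replicate x
    method (x cutoff for cutoff sweeps).

    ``methods`` may include ``"true"`` to score the oracle factor c = S2/S1.
    ``config_overrides`` adjusts base generator fields (e.g. a smaller
    ``n_orth``) for scaled-down runs.  Deterministic under ``seed``.
    """
    design = study_configs()[study] if isinstance(study, str) else study
    values = list(sweep_values) if sweep_values is not None else list(design.sweep_values)
    cut = design.cutoff if cutoff is None else cutoff
    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    cutoff_sweep = design.sweep_param == "cutoff"
    outer = [None] if cutoff_sweep else values
    for sv in outer:
        for rep in range(reps):
            cfg = design.config
            if not cutoff_sweep:
                cfg = replace(cfg, **{design.sweep_param: sv})
            if config_overrides:
                cfg = replace(cfg, **config_overrides)
            cfg = replace(cfg, seed=int(rng.integers(2**31)))
            table, conserved, truth = simulate_dataset(cfg)
            keep = ~truth.unique_mask
            for method in methods:
                c = (
                    truth.c_true
                    if method == "true"
                    else _fit_factor(method, table, conserved, alpha)
                )
                pv = test_all(table, c).pvalues[keep]
                dm = truth.de_mask[keep]
                for cu in values if cutoff_sweep else [cut]:
                    row = prf_metrics(pv, dm, cu, method=method, replicate=rep)
                    rows.append(
                        {
                            "study": design.name,
                            "sweep_param": design.sweep_param,
                            "sweep_value": cu if cutoff_sweep else sv,
                            "method": method,
                            "replicate": rep,
                            "cutoff": cu,
                            "c_est": c,
                            "c_true": truth.c_true,
                            "fd_number": row.fd_number,
                            "precision": row.precision,
                            "sensitivity": row.sensitivity,
                            "fscore": row.fscore,
                        }
                    )
    return pd.DataFrame(rows)


def summarize_study(results: pd.DataFrame) -> pd.DataFrame:
    """Per-method means over replicates (NaN metrics excluded from means)."""
    return (
        results.groupby(["study", "sweep_param", "sweep_value", "method"])[
            ["fd_number", "precision", "sensitivity", "fscore", "c_est"]
        ]
        .mean()
        .reset_index()
    )


def real_data_summary(
    table_path: str | Path,
    conserved_path: str | Path,
    eval_set_paths: dict[str, str | Path] | None = None,
    cutoff: float = 1e-6,
    alpha: float = 0.05,
) -> dict:
    """End-to-end real-data pipeline.

    Reads an ortholog count/length table and a conserved anchor list,
    filters transcripts, estimates the scaling factor by both methods,
    tests every ortholog at the fitted factors, and reports DE-call counts
    at the cutoff plus assumed-null FDRs against each evaluation set (e.g.
    the 500 and 1000 most conserved transcripts).
    """
    raw = read_ortholog_table(table_path)
    table = filter_transcripts(raw)
    conserved = read_conserved_list(conserved_path, table)
    out: dict = {
        "n_input": len(raw),
        "n_retained": len(table),
        "m_conserved": conserved.m,
        "mean_length_difference": float(
            np.mean(np.abs(table.data["L1"] - table.data["L2"]))
        ),
        "methods": {},
    }
    for method in ("scbn", "median"):
        c = _fit_factor(method, table, conserved, alpha)
        pv = test_all(table, c).pvalues
        entry: dict = {
            "c": c,
            "n_de_calls": int(np.sum(pv < cutoff)),
            "fdr": {},
        }
        if eval_set_paths:
            for name, p in eval_set_paths.items():
                es = read_conserved_list(p, table)
                in_set = table.gene_ids.isin(set(es.ids)).to_numpy()
                calls = pv < cutoff
                entry["fdr"][name] = {
                    "false_calls": int(np.sum(calls & in_set)),
                    "total_calls": int(calls.sum()),
                    "fdr": assumed_null_fdr(pv, es, table, cutoff),
                }
        out["methods"][method] = entry
    return out
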