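"""Synthetic two-species RNA-seq data with known truth.

The generator draws per-gene relative expression rates and per-species
gene lengths, assigns a DE fraction with chosen fold and direction, adds
unique genes (orthologous but expressed in one species only) and unmapped
genes (present in one species' genome only, hence outside the ortholog
table), and emits Poisson counts under the mean model

    E(X_gt) = mu_gt * L_gt / S_t * N_t,      S_t = sum_g mu_gt * L_gt,

so the true scaling factor c = S2/S1 is known exactly.  A conserved anchor
set of configurable size is drawn from the non-DE genes, optionally
contaminated with a chosen fraction of DE genes ("noise rate").

Seven named study parameterizations mirror the standard simulation
benchmark (DE fraction, fold, direction balance, unique/unmapped gene
numbers, conserved-set size, noise sweeps, cutoff sweeps).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import ConservedSet, OrthologTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "StudyDesign",
    "simulate_dataset",
    "study_configs",
    "write_truth",
    "write_provenance",
]


@dataclass
class SimConfig:
    """Generator parameters.

    Defaults are the benchmark's base conditions: 10000 orthologous genes,
    10% DE at 1.2-fold with 90% up-regulated in species 2, 1000/2000 unique
    genes, 2000/4000 unmapped genes, 1000 conserved genes with no noise,
    expected orthologous depths of 1e7 and 2e7 reads.  Lengths are
    log-uniform on [200, 20000] bases, with species-2 lengths scaled by
    ``length_scale_sp2`` (default 2.0, which sets the true scaling factor
    c = S2/S1 near 2 — c is identifiable only through the recorded
    lengths).  Relative expression rates default to a log-normal(0, 1.5)
    stand-in for an empirical count-rate distribution; an empirical rate
    vector may be supplied instead via ``rate_values``.
    """

    n_orth: int = 10000
    prop_de: float = 0.1
    fold: float = 1.2
    prop_up_sp2: float = 0.9
    n_unique: tuple[int, int] = (1000, 2000)
    n_unmapped: tuple[int, int] = (2000, 4000)
    m_conserved: int = 1000
    noise_rate: float = 0.0
    depth: tuple[float, float] = (10_000_000.0, 20_000_000.0)
    length_range: tuple[float, float] = (200.0, 20000.0)
    length_scale_sp2: float = 2.0
    rate_sigma: float = 1.5
    rate_values: np.ndarray | None = None
    seed: int | None = None

    def validate(self) -> None:
        if self.n_orth < 1:
            raise ValueError("n_orth must be >= 1")
        for name in ("prop_de", "prop_up_sp2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0.0 <= self.noise_rate <= 0.6):
            raise ValueError("noise_rate must lie in [0, 0.6]")
        if self.fold < 1.0:
            raise ValueError("fold must be >= 1")
        if any(v < 0 for v in (*self.n_unique, *self.n_unmapped)):
            raise ValueError("gene counts must be >= 0")
        if not (1 <= self.m_conserved <= self.n_orth):
            raise ValueError("m_conserved must lie in [1, n_orth]")
        if any(d <= 0 for d in self.depth):
            raise ValueError("depths must be > 0")
        n_de = int(round(self.prop_de * self.n_orth))
        n_noise = int(round(self.noise_rate * self.m_conserved))
        if n_noise > n_de:
            raise ValueError(
                f"conserved noise needs {n_noise} DE genes but only {n_de} exist"
            )
        if self.m_conserved - n_noise > self.n_orth - n_de:
            raise ValueError("not enough non-DE genes for the clean conserved set")

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["rate_values"] is not None:
            d["rate_values"] = list(map(float, d["rate_values"]))
        return d


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset."""

    gene_id: np.ndarray
    de_mask: np.ndarray
    direction: np.ndarray  # +1 up in species 2, -1 down, 0 non-DE
    unique_mask: np.ndarray
    mu1: np.ndarray
    mu2: np.ndarray
    c_true: float
    config: SimConfig
    unmapped_counts: tuple[np.ndarray, np.ndarray] = field(
        default_factory=lambda: (np.array([]), np.array([]))
    )


def _draw_lengths(rng: np.random.Generator, n: int, lo: float, hi: float,
                  scale: float = 1.0) -> np.ndarray:
    L = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)) * scale
    return np.maximum(np.rint(L), 1.0).astype(np.int64)


def _draw_rates(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    if cfg.rate_values is not None:
        vals = np.asarray(cfg.rate_values, dtype=float)
        return vals[rng.integers(0, len(vals), size=n)]
    return rng.lognormal(mean=0.0, sigma=cfg.rate_sigma, size=n)


def simulate_dataset(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[OrthologTable, ConservedSet, SimTruth]:
    """Generate one dataset: ortholog table, conserved anchor set, truth.

    Row layout: ``n_orth`` regular orthologs first, then the species-1-only
    and species-2-only unique genes.  Unmapped genes are simulated per
    species for library-size realism but are *excluded* from the table and
    from the orthologous depths N_t (N_t counts orthologous reads only).
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    nu1, nu2 = config.n_unique
    n_total = config.n_orth + nu1 + nu2
    mu = _draw_rates(rng, n_total, config)
    lo, hi = config.length_range
    L1 = _draw_lengths(rng, n_total, lo, hi)
    L2 = _draw_lengths(rng, n_total, lo, hi, scale=config.length_scale_sp2)

    idx_orth = np.arange(config.n_orth)
    idx_u1 = np.arange(config.n_orth, config.n_orth + nu1)
    idx_u2 = np.arange(config.n_orth + nu1, n_total)

    mu1 = mu.copy()
    mu2 = mu.copy()
    mu1[idx_u2] = 0.0  # species-2-only unique genes
    mu2[idx_u1] = 0.0  # species-1-only unique genes

    n_de = int(round(config.prop_de * config.n_orth))
    de_idx = rng.choice(idx_orth, size=n_de, replace=False)
    up = rng.random(n_de) < config.prop_up_sp2
    mu2[de_idx[up]] = mu1[de_idx[up]] * config.fold
    mu2[de_idx[~up]] = mu1[de_idx[~up]] / config.fold

    direction = np.zeros(n_total, dtype=np.int8)
    direction[de_idx[up]] = 1
    direction[de_idx[~up]] = -1
    direction[idx_u1] = -1  # expressed in species 1 only
    direction[idx_u2] = 1

    unique_mask = np.zeros(n_total, dtype=bool)
    unique_mask[idx_u1] = True
    unique_mask[idx_u2] = True

    de_mask = np.zeros(n_total, dtype=bool)
    de_mask[de_idx] = True
    de_mask |= unique_mask  # unique genes are genuinely DE (mu1 != mu2)

    S1 = float(np.sum(mu1 * L1))
    S2 = float(np.sum(mu2 * L2))
    c_true = S2 / S1

    lam1 = mu1 * L1 / S1 * config.depth[0]
    lam2 = mu2 * L2 / S2 * config.depth[1]
    x1 = rng.poisson(lam1)
    x2 = rng.poisson(lam2)

    # Unmapped genes: one species' genome only; reported, never in the table.
    um1_mu = _draw_rates(rng, config.n_unmapped[0], config)
    um1_L = _draw_lengths(rng, config.n_unmapped[0], lo, hi)
    um2_mu = _draw_rates(rng, config.n_unmapped[1], config)
    um2_L = _draw_lengths(rng, config.n_unmapped[1], lo, hi,
                          scale=config.length_scale_sp2)
    um1 = rng.poisson(um1_mu * um1_L / S1 * config.depth[0])
    um2 = rng.poisson(um2_mu * um2_L / S2 * config.depth[1])

    gene_id = np.array([f"g{i:06d}" for i in range(n_total)])
    table = OrthologTable(
        pd.DataFrame(
            {
                "gene_id": gene_id,
                "x1": x1.astype(np.int64),
                "L1": L1,
                "x2": x2.astype(np.int64),
                "L2": L2,
            }
        )
    )

    n_noise = int(round(config.noise_rate * config.m_conserved))
    nonde_idx = idx_orth[~de_mask[idx_orth]]
    clean = rng.choice(nonde_idx, size=config.m_conserved - n_noise, replace=False)
    noisy = (
        rng.choice(de_idx, size=n_noise, replace=False)
        if n_noise > 0
        else np.array([], dtype=int)
    )
    conserved_idx = np.sort(np.concatenate([clean, noisy]))
    conserved = ConservedSet(ids=[gene_id[i] for i in conserved_idx])

    truth = SimTruth(
        gene_id=gene_id,
        de_mask=de_mask,
        direction=direction,
        unique_mask=unique_mask,
        mu1=mu1,
        mu2=mu2,
        c_true=c_true,
        config=config,
        unmapped_counts=(um1, um2),
    )
    return table, conserved, truth


def write_truth(truth: SimTruth, path: str | Path) -> None:
    """Truth sidecar as TSV: gene_id, de, direction, unique, mu1, mu2."""
    df = pd.DataFrame(
        {
            "gene_id": truth.gene_id,
            "de": truth.de_mask.astype(int),
            "direction": truth.direction,
            "unique": truth.unique_mask.astype(int),
            "mu1": truth.mu1,
            "mu2": truth.mu2,
        }
    )
    with open(Path(path), "w") as fh:
        fh.write(f"# c_true = {truth.c_true!r}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_provenance(config: SimConfig, path: str | Path, **extra) -> None:
    """Full generator configuration (plus seed) as YAML."""
    payload = {"config": config.to_dict(), **extra}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


@dataclass
class StudyDesign:
    """One named study: a base configuration plus a one-parameter sweep."""

    name: str
    config: SimConfig
    sweep_param: str
    sweep_values: tuple
    cutoff: float = 0.01


def study_configs() -> dict[str, StudyDesign]:
    """The seven benchmark study parameterizations.

    Base conditions (Study 1): 10% DE at 1.2-fold, 90% up-regulated in
    species 2, 1000/2000 unique genes, 2000/4000 unmapped genes.  Sweeps:
    conserved-set size (1), conserved-set noise (2, 5, 6 at fold 1.5 with
    m = 1000; 3 at 20% DE, 8-fold, 70% up), p-value cutoff (4, 40% DE),
    and DE fraction (7, noise 0.2).
    """
    base = SimConfig()
    f15 = replace(base, fold=1.5, m_conserved=1000)
    noise_grid = tuple(np.round(np.arange(0.0, 0.61, 0.1), 1))
    return {
        "study1": StudyDesign(
            "study1", base, "m_conserved", (50, 100, 200, 300, 500, 700, 1000)
        ),
        "study2": StudyDesign("study2", f15, "noise_rate", noise_grid),
        "study3": StudyDesign(
            "study3",
            replace(base, prop_de=0.2, fold=8.0, prop_up_sp2=0.7),
            "noise_rate",
            (0.0, 0.4),
        ),
        "study4": StudyDesign(
            "study4",
            replace(base, prop_de=0.4),
            "cutoff",
            (0.0001, 0.001, 0.01, 0.05, 0.1, 0.2, 0.4, 0.6),
        ),
        "study5": StudyDesign(
            "study5", f15, "noise_rate", tuple(np.round(np.arange(0.0, 0.51, 0.1), 1))
        ),
        "study6": StudyDesign("study6", f15, "noise_rate", noise_grid, cutoff=0.01),
        "study7": StudyDesign(
            "study7",
            replace(base, fold=1.5, noise_rate=0.2),
            "prop_de",
            (0.1, 0.2, 0.3, 0.4, 0.5, 0.6),
        ),
    }
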