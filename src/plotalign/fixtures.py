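"""Synthetic fixture generators emulating the data shapes the engine is
exercised on: block-structured expression-like matrices (clustered-heatmap
case), sample x gene alteration tables (oncoprint case), and hierarchical
taxa-abundance compositions (microbiome case).

Every generator is a pure function of its integer seed (one fresh
:func:`numpy.random.default_rng` per call, no global state), so figures and
tests built on them are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import LabeledMatrix
from .plots import AlterationRecord

__all__ = [
    "synth_block_matrix",
    "synth_alterations",
    "synth_abundance",
    "BlockMatrix",
    "AbundanceTables",
]


@dataclass(frozen=True)
class BlockMatrix:
    """A block-structured matrix plus the planted block labels."""

    matrix: LabeledMatrix
    row_blocks: dict[str, int]
    col_blocks: dict[str, int]


def synth_block_matrix(
    n_rows: int = 60,
    n_cols: int = 20,
    k_row_blocks: int = 3,
    k_col_blocks: int = 2,
    effect: float = 10.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> BlockMatrix:
    """Matrix whose cell value is its (row block, column block) mean plus
    Gaussian noise; block means are spaced by ``effect`` so agglomerative
    clustering can recover the planted structure.

    Rows and columns are assigned to blocks in a seeded shuffle, so the
    planted structure is not trivially contiguous in input order.
    """
    if not (1 <= k_row_blocks <= n_rows and 1 <= k_col_blocks <= n_cols):
        raise ValueError("block counts must satisfy 1 <= k <= n")
    rng = np.random.default_rng(seed)
    row_lab = np.repeat(np.arange(k_row_blocks), -(-n_rows // k_row_blocks))[:n_rows]
    col_lab = np.repeat(np.arange(k_col_blocks), -(-n_cols // k_col_blocks))[:n_cols]
    rng.shuffle(row_lab)
    rng.shuffle(col_lab)
    means = effect * (row_lab[:, None] + col_lab[None, :])
    values = means + rng.normal(0.0, noise_sd, size=(n_rows, n_cols))
    row_ids = tuple(f"r{i:03d}" for i in range(n_rows))
    col_ids = tuple(f"c{j:03d}" for j in range(n_cols))
    return BlockMatrix(
        matrix=LabeledMatrix(values, row_ids, col_ids),
        row_blocks={row_ids[i]: int(row_lab[i]) for i in range(n_rows)},
        col_blocks={col_ids[j]: int(col_lab[j]) for j in range(n_cols)},
    )


def synth_alterations(
    n_samples: int,
    genes: Mapping[str, float],
    type_mix: Mapping[str, float] | None = None,
    seed: int = 0,
) -> list[AlterationRecord]:
    """Bernoulli alteration per (sample, gene) at the gene's rate; each event
    gets a type drawn from ``type_mix`` (probabilities, normalized)."""
    for g, r in genes.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rate for gene {g!r} must be in [0, 1], got {r}")
    if type_mix is None:
        type_mix = {"MUT": 0.6, "AMP": 0.2, "DEL": 0.2}
    types = list(type_mix)
    probs = np.asarray([type_mix[t] for t in types], dtype=float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ValueError("type mix must hold non-negative weights, not all zero")
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    out: list[AlterationRecord] = []
    for s in samples:
        for g, rate in genes.items():
            if rng.random() < rate:
                t = types[rng.choice(len(types), p=probs)]
                out.append(AlterationRecord(sample=s, gene=g, type=t))
    return out


@dataclass(frozen=True)
class AbundanceTables:
    """Per-sample compositions at two taxonomic ranks plus metadata."""

    phylum: LabeledMatrix  # samples x phyla, rows sum to 1
    genus: LabeledMatrix  # samples x genera, genera sum to their phylum
    hierarchy: dict[str, tuple[str, ...]]  # phylum -> genera
    sample_groups: dict[str, str]


def synth_abundance(
    n_samples_per_group: int,
    groups: Sequence[str],
    taxa: Mapping[str, Sequence[str]],
    concentration: float = 20.0,
    group_effect: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
) -> AbundanceTables:
    """Two-rank compositional abundances (phylum -> genera).

    Per sample, phylum proportions are Dirichlet with concentration
    ``concentration * base * multiplier``, where ``group_effect`` maps
    group -> phylum -> multiplicative shift of that phylum's concentration
    (the planted differential-abundance signal). Each phylum's mass is then
    split among its genera by a second Dirichlet draw, so genus values sum
    to their phylum value exactly.
    """
    if not taxa:
        raise ValueError("taxa hierarchy must be non-empty")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    phyla = list(taxa)
    genera = [g for p in phyla for g in taxa[p]]
    base = np.ones(len(phyla))
    group_effect = group_effect or {}

    sample_ids: list[str] = []
    sample_groups: dict[str, str] = {}
    ph_rows: list[np.ndarray] = []
    ge_rows: list[np.ndarray] = []
    for grp in groups:
        mult = np.asarray(
            [group_effect.get(grp, {}).get(p, 1.0) for p in phyla], dtype=float
        )
        alpha = concentration * base * mult
        for i in range(n_samples_per_group):
            sid = f"{grp}_{i:03d}"
            sample_ids.append(sid)
            sample_groups[sid] = grp
            ph = rng.dirichlet(alpha)
            ph_rows.append(ph)
            ge = []
            for k, p in enumerate(phyla):
                n_g = len(taxa[p])
                split = rng.dirichlet(np.ones(n_g) * 5.0) if n_g > 1 else np.ones(1)
                ge.extend(ph[k] * split)
            ge_rows.append(np.asarray(ge))

    return AbundanceTables(
        phylum=LabeledMatrix(np.vstack(ph_rows), tuple(sample_ids), tuple(phyla)),
        genus=LabeledMatrix(np.vstack(ge_rows), tuple(sample_ids), tuple(genera)),
        hierarchy={p: tuple(taxa[p]) for p in phyla},
        sample_groups=sample_groups,
    )
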