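"""Synthetic labeled sequence sets with controllable class separation.

Classes are order-1 Markov chains over A/C/G/T — the minimal model giving
class-distinct k-mer spectra for every k >= 2 — and divergence series are
built by point-mutating a common ancestor at a range of substitution
rates, optionally with indels.  Everything is reproducible from
(parameters, seed), and emitted datasets flow through the same FASTA/TSV
surface as real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import LabeledDataset, SequenceRecord

__all__ = [
    "ClassModel",
    "DivergenceSeries",
    "random_class_models",
    "generate_class_dataset",
    "mutate",
    "make_divergence_series",
]

_BASES = np.array(list("ACGT"))


@dataclass
class ClassModel:
    """One sequence class: an order-1 Markov chain over A/C/G/T."""

    label: str
    transition_matrix: np.ndarray  # 4x4 row-stochastic, rows/cols in ACGT order
    initial_distribution: np.ndarray  # length 4, sums to 1

    def __post_init__(self) -> None:
        P = np.asarray(self.transition_matrix, dtype=float)
        pi = np.asarray(self.initial_distribution, dtype=float)
        if P.shape != (4, 4):
            raise ValueError(f"transition matrix must be 4x4, got {P.shape}")
        if (P < 0).any() or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must be non-negative and sum to 1")
        if pi.shape != (4,) or (pi < 0).any() or not np.isclose(pi.sum(), 1.0):
            raise ValueError("initial distribution must be 4 non-negatives summing to 1")
        self.transition_matrix = P
        self.initial_distribution = pi


@dataclass
class DivergenceSeries:
    """Plan for a mutant series around one ancestor, one label per rate."""

    ancestor: SequenceRecord
    rates: list[float]
    replicates: int = 20
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if sorted(self.rates) != list(self.rates):
            raise ValueError("rates must be sorted ascending")
        if any(not 0.0 <= r <= 1.0 for r in self.rates):
            raise ValueError("rates must lie in [0, 1]")


def random_class_models(
    n_classes: int, seed: int, divergence: float = 1.0, label_prefix: str = "class"
) -> list[ClassModel]:
    """Seeded random class models with a separation knob.

    Each transition matrix is drawn row-wise from Dirichlet(1, 1, 1, 1),
    then blended with the uniform chain: ``divergence`` = 1 keeps the raw
    draws (well-separated classes), 0 collapses every class onto the same
    uniform chain (indistinguishable classes).
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    uniform = np.full((4, 4), 0.25)
    models = []
    for c in range(n_classes):
        P = rng.dirichlet(np.ones(4), size=4)
        P = divergence * P + (1.0 - divergence) * uniform
        models.append(
            ClassModel(
                label=f"{label_prefix}{c}",
                transition_matrix=P,
                initial_distribution=np.full(4, 0.25),
            )
        )
    return models


def _sample_chain(model: ClassModel, n: int, length: int, rng) -> list[str]:
    """Draw n sequences of the given length from one chain, vectorized over n."""
    cum_init = np.cumsum(model.initial_distribution)
    cum_rows = np.cumsum(model.transition_matrix, axis=1)
    states = np.empty((n, length), dtype=np.int64)
    u = rng.random((n, length))
    states[:, 0] = np.searchsorted(cum_init, u[:, 0], side="right")
    for j in range(1, length):
        # one vectorized step: compare each row's uniform to its state's CDF
        states[:, j] = (u[:, j, None] >= cum_rows[states[:, j - 1]]).sum(axis=1)
    np.clip(states, 0, 3, out=states)
    return ["".join(row) for row in _BASES[states]]


def generate_class_dataset(
    models: list[ClassModel],
    n_per_class: int = 100,
    length: int = 500,
    seed: int = 0,
) -> LabeledDataset:
    """Labeled dataset of Markov-chain sequences, n_per_class from each model."""
    if length < 1 or n_per_class < 1:
        raise ValueError("length and n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    records, labels = [], []
    for model in models:
        for i, seq in enumerate(_sample_chain(model, n_per_class, length, rng)):
            records.append(SequenceRecord(id=f"{model.label}_{i}", residues=seq))
            labels.append(model.label)
    return LabeledDataset(records=records, labels=labels, level_name="synthetic")


def mutate(
    seq: SequenceRecord,
    sub_rate: float,
    indel_rate: float = 0.0,
    seed: int = 0,
    new_id: str | None = None,
) -> SequenceRecord:
    """Point-mutate a sequence: independent substitutions plus optional indels.

    Each position is substituted with probability ``sub_rate`` (uniform
    over the three alternative bases).  Indels split ``indel_rate`` evenly:
    each position is deleted with probability indel_rate/2 and a uniform
    random base is inserted before it with probability indel_rate/2.
    """
    if not 0.0 <= sub_rate <= 1.0 or not 0.0 <= indel_rate <= 1.0:
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lut = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    codes = lut[np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError("mutate requires an unambiguous A/C/G/T sequence")
    n = len(codes)

    sub_mask = rng.random(n) < sub_rate
    offsets = rng.integers(1, 4, size=n)  # never maps a base to itself
    codes = np.where(sub_mask, (codes + offsets) % 4, codes)

    if indel_rate > 0.0:
        keep = rng.random(n) >= indel_rate / 2.0
        insert = rng.random(n) < indel_rate / 2.0
        inserted = rng.integers(0, 4, size=n)
        pieces = []
        for j in range(n):
            if insert[j]:
                pieces.append(inserted[j])
            if keep[j]:
                pieces.append(codes[j])
        codes = np.asarray(pieces, dtype=np.int64)
        if codes.size == 0:  # fully deleted: keep one random base, not an empty record
            codes = rng.integers(0, 4, size=1)
    return SequenceRecord(
        id=new_id or f"{seq.id}_mut", residues="".join(_BASES[codes])
    )


def make_divergence_series(spec: DivergenceSeries, seed: int = 0) -> LabeledDataset:
    """Mutant replicates at each rate, labeled by rate bin, ancestor included.

    The ancestor is the first record with label ``"ancestor"``; each mutant
    is labeled ``rate=<r>`` so label bins align with the divergence level.
    """
    rng = np.random.default_rng(seed)
    records = [spec.ancestor]
    labels = ["ancestor"]
    for rate in spec.rates:
        for rep in range(spec.replicates):
            child_seed = int(rng.integers(0, 2**31 - 1))
            records.append(
                mutate(
                    spec.ancestor,
                    sub_rate=rate,
                    indel_rate=spec.indel_rate,
                    seed=child_seed,
                    new_id=f"{spec.ancestor.id}_r{rate:g}_{rep}",
                )
            )
            labels.append(f"rate={rate:g}")
    return LabeledDataset(records=records, labels=labels, level_name="divergence")
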