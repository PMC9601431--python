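"""Seeded Markov-chain sequence generators for testing and benchmarking.

Real two-class sequence benchmarks (coding vs. non-coding RNA, promoter vs.
non-promoter, ...) differ in k-mer composition; these fixtures emulate that
with order-m Markov chains whose transition matrices are chosen to produce
controllable compositional separation. They make every other module
testable without downloading anything.

Because the entropy features are permutation-invariant in the symbols, two
chains that are mirror images of each other (pure GC-rich vs. its AT-rich
reflection) would be indistinguishable to the method; the separable pair
therefore contrasts a strongly skewed, low-entropy GC-rich chain with a
mildly skewed, higher-entropy AT-rich one.

All randomness flows from one integer seed: per-class streams are derived
with numpy's SeedSequence spawning, so classes are independent yet the whole
dataset is reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import SYMBOL_ORDER, Alphabet, SequenceRecord, write_fasta

__all__ = ["MarkovClassSpec", "generate_class", "make_benchmark", "worked_examples"]

BENCHMARK_KINDS = ("separable_pair", "null_pair", "multiclass3")


@dataclass
class MarkovClassSpec:
    """One class of sequences drawn from an order-m Markov chain.

    ``transition`` has shape (|A|,)*order + (|A|,): the last axis is the
    next-symbol distribution given the preceding ``order`` symbols (a plain
    probability vector for order 0). Lengths are uniform integers in
    ``length_range`` inclusive.
    """

    label: str
    transition: np.ndarray
    alphabet: Alphabet = Alphabet.DNA
    order: int = 1
    length_range: tuple[int, int] = (200, 500)
    n_sequences: int = 50
    seed: int = 0

    def __post_init__(self):
        self.transition = np.asarray(self.transition, dtype=float)
        a = len(SYMBOL_ORDER[self.alphabet])
        want = (a,) * self.order + (a,)
        if self.transition.shape != want:
            raise ValueError(
                f"transition shape {self.transition.shape} != {want} for order "
                f"{self.order} over a {a}-symbol alphabet"
            )
        rows = self.transition.reshape(-1, a)
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("every transition row must sum to 1 (within 1e-12)")
        if (rows < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid length range {self.length_range}")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")


def _sample_sequence(spec: MarkovClassSpec, length: int, rng: np.random.Generator) -> str:
    symbols = SYMBOL_ORDER[spec.alphabet]
    a = len(symbols)
    out = np.empty(length, dtype=np.int64)
    # uniform start: the first `order` symbols are drawn uniformly
    m = min(spec.order, length)
    out[:m] = rng.integers(0, a, size=m)
    rows = spec.transition.reshape(-1, a)
    cum = rows.cumsum(axis=1)
    strides = a ** np.arange(spec.order - 1, -1, -1) if spec.order else np.empty(0, dtype=int)
    for i in range(m, length):
        if spec.order == 0:
            row = 0
        else:
            ctx = out[i - spec.order : i]
            row = int((ctx * strides).sum())
        out[i] = np.searchsorted(cum[row], rng.random(), side="right")
    return "".join(symbols[s] for s in out)


def generate_class(spec: MarkovClassSpec, fasta_path: str | Path | None = None) -> list[SequenceRecord]:
    """Sample ``spec.n_sequences`` records; optionally also write FASTA.

    Record ids are ``<label>_<index>``. Reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    records = []
    for i in range(spec.n_sequences):
        length = int(rng.integers(lo, hi + 1))
        residues = _sample_sequence(spec, length, rng)
        records.append(
            SequenceRecord(
                id=f"{spec.label}_{i}",
                residues=residues,
                alphabet=spec.alphabet,
                label=spec.label,
            )
        )
    if fasta_path is not None:
        write_fasta(records, fasta_path)
    return records


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary symbol distribution of an order-1 chain (left eigenvector)."""
    t = np.asarray(transition, dtype=float)
    vals, vecs = np.linalg.eig(t.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    return pi / pi.sum()


def _tile(row: list[float]) -> np.ndarray:
    return np.tile(np.asarray(row, dtype=float), (4, 1))


# Order-1 transition matrices for the built-in benchmarks (A, C, G, T order).
# separable: strong-GC (low entropy) vs mild-AT (higher entropy) — distinct
# entropy signatures at every k. null: one shared uniform chain for both
# labels. multiclass: a third, self-transition-heavy chain whose 1-mer
# entropy matches the uniform chain but whose higher-k entropies do not.
SEPARABLE_GC = np.array(
    [
        [0.10, 0.40, 0.40, 0.10],
        [0.05, 0.50, 0.40, 0.05],
        [0.05, 0.40, 0.50, 0.05],
        [0.10, 0.40, 0.40, 0.10],
    ]
)
SEPARABLE_AT = np.array(
    [
        [0.40, 0.15, 0.15, 0.30],
        [0.35, 0.15, 0.15, 0.35],
        [0.35, 0.15, 0.15, 0.35],
        [0.30, 0.15, 0.15, 0.40],
    ]
)
NULL_UNIFORM = _tile([0.25, 0.25, 0.25, 0.25])
MULTICLASS_SKEWED = _tile([0.55, 0.15, 0.15, 0.15])
MULTICLASS_REPETITIVE = 0.7 * np.eye(4) + 0.1 * (1 - np.eye(4))


def make_benchmark(
    kind: str,
    n_per_class: int = 100,
    seed: int = 0,
    length_range: tuple[int, int] = (200, 500),
    out_dir: str | Path | None = None,
) -> tuple[list[SequenceRecord], dict]:
    """Generate a labeled benchmark set plus a parameter manifest.

    kind="separable_pair"
        Two order-1 chains with distinct transition matrices (strongly
        GC-skewed vs. mildly AT-skewed); classifiers should separate them.
    kind="null_pair"
        Both labels drawn from one uniform chain; any classifier should sit
        at chance.
    kind="multiclass3"
        Three distinct chains (uniform, skewed, repetitive) for the
        multiclass metrics path.

    If ``out_dir`` is given, one FASTA per class and a ``manifest.json``
    recording every parameter and seed are written there.
    """
    if n_per_class < 10:
        raise ValueError("n_per_class must be >= 10")
    if kind == "separable_pair":
        mats = {"gc_rich": SEPARABLE_GC, "at_rich": SEPARABLE_AT}
    elif kind == "null_pair":
        mats = {"null_a": NULL_UNIFORM, "null_b": NULL_UNIFORM}
    elif kind == "multiclass3":
        mats = {
            "uniform": NULL_UNIFORM,
            "skewed": MULTICLASS_SKEWED,
            "repetitive": MULTICLASS_REPETITIVE,
        }
    else:
        raise ValueError(f"unknown benchmark kind {kind!r}; choose from {BENCHMARK_KINDS}")

    child_seeds = np.random.SeedSequence(seed).generate_state(len(mats)) % (2**31)
    records: list[SequenceRecord] = []
    manifest: dict = {"kind": kind, "seed": int(seed), "n_per_class": n_per_class,
                      "length_range": list(length_range), "order": 1, "classes": {}}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for (label, mat), child in zip(mats.items(), child_seeds):
        spec = MarkovClassSpec(
            label=label,
            transition=mat,
            order=1,
            length_range=length_range,
            n_sequences=n_per_class,
            seed=int(child),
        )
        fasta = out_dir / f"{label}.fasta" if out_dir is not None else None
        records.extend(generate_class(spec, fasta_path=fasta))
        manifest["classes"][label] = {
            "seed": int(child),
            "transition": mat.tolist(),
            "fasta": f"{label}.fasta" if out_dir is not None else None,
        }
    if out_dir is not None:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return records, manifest


def worked_examples() -> list[SequenceRecord]:
    """The small fixed records used throughout the worked examples."""
    return [
        SequenceRecord(id="ex_acgtacgt", residues="ACGTACGT", alphabet=Alphabet.DNA),
        SequenceRecord(id="ex_allA", residues="AAAAAAAA", alphabet=Alphabet.DNA),
        SequenceRecord(id="ex_acgt", residues="ACGT", alphabet=Alphabet.DNA),
        SequenceRecord(id="ex_masked", residues="ACNGT", alphabet=Alphabet.DNA),
        SequenceRecord(id="ex_protein", residues="MKVL", alphabet=Alphabet.PROTEIN),
    ]
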