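"""Classification-head architecture enumeration and hyperparameter grids.

Heads connect a fixed 1000-wide feature vector to a 2-class output through a
strictly decreasing chain of hidden widths drawn from the halving pool
(512, 256, 128, 64, 32, 16, 8, 4). Three generators are provided:

* ``halving_chains`` — prefixes of the pool, depths 0..8 (9 chains);
* ``skip_one_variants`` — every single-hidden-layer omission from those
  chains, deduplicated (28 new);
* ``contiguous_skip_variants`` — omission of every contiguous run of 2..7
  hidden layers from the deepest chain, deduplicated (21 new);

for 58 distinct architectures in total.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, fields
from typing import Any, Iterable, Sequence

__all__ = [
    "CandidateRecord",
    "HeadArchitecture",
    "HyperParamGrid",
    "all_architectures",
    "contiguous_skip_variants",
    "enumerate_grid",
    "halving_chains",
    "select_top_candidate",
    "skip_one_variants",
    "table8_grid",
]

HALVING_POOL: tuple[int, ...] = (512, 256, 128, 64, 32, 16, 8, 4)


@dataclass(frozen=True)
class HeadArchitecture:
    hidden_widths: tuple[int, ...] = ()
    input_width: int = 1000
    output_width: int = 2

    def __post_init__(self) -> None:
        widths = tuple(int(w) for w in self.hidden_widths)
        object.__setattr__(self, "hidden_widths", widths)
        if any(w not in HALVING_POOL for w in widths):
            raise ValueError(f"hidden widths must come from {HALVING_POOL}")
        if any(a <= b for a, b in zip(widths, widths[1:])):
            raise ValueError("hidden widths must be strictly decreasing")

    @property
    def widths(self) -> tuple[int, ...]:
        return (self.input_width, *self.hidden_widths, self.output_width)

    @property
    def n_layers(self) -> int:
        """Layer count including input and output layers."""
        return len(self.widths)

    @property
    def param_count(self) -> int:
        """Dense parameters (weights + biases) along the chain."""
        w = self.widths
        return sum((a + 1) * b for a, b in zip(w, w[1:]))

    @property
    def name(self) -> str:
        return "-".join(str(w) for w in self.widths)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def _canonical(archs: Iterable[HeadArchitecture]) -> list[HeadArchitecture]:
    """Sort by depth, then lexicographically by the hidden widths."""
    return sorted(set(archs), key=lambda a: (len(a.hidden_widths), a.hidden_widths))


def halving_chains() -> list[HeadArchitecture]:
    """The 9 prefix chains of the halving pool (depths 0 through 8)."""
    return [HeadArchitecture(HALVING_POOL[:m]) for m in range(len(HALVING_POOL) + 1)]


def skip_one_variants(
    chains: Sequence[HeadArchitecture] | None = None,
) -> list[HeadArchitecture]:
    """Every single-hidden-layer omission from the chains, minus duplicates.

    Omitting the last hidden layer of a chain reproduces the next-shallower
    chain, so 36 raw omissions collapse to 28 new architectures.
    """
    if chains is None:
        chains = halving_chains()
    existing = set(chains)
    out: set[HeadArchitecture] = set()
    for chain in chains:
        h = chain.hidden_widths
        for i in range(len(h)):
            variant = HeadArchitecture(h[:i] + h[i + 1 :])
            if variant not in existing:
                out.add(variant)
    return _canonical(out)


def contiguous_skip_variants(
    k_min: int = 2, k_max: int = 7
) -> list[HeadArchitecture]:
    """Omit every contiguous run of ``k`` hidden layers (k_min..k_max) from
    the deepest halving chain; deduplicated against all earlier generators.
    """
    chains = halving_chains()
    previous = set(chains) | set(skip_one_variants(chains))
    deepest = chains[-1].hidden_widths
    out: set[HeadArchitecture] = set()
    for k in range(k_min, k_max + 1):
        for start in range(len(deepest) - k + 1):
            variant = HeadArchitecture(deepest[:start] + deepest[start + k :])
            if variant not in previous:
                out.add(variant)
    return _canonical(out)


def all_architectures() -> list[HeadArchitecture]:
    """The full set from all three generators (58), canonically ordered."""
    chains = halving_chains()
    return _canonical(
        set(chains) | set(skip_one_variants(chains)) | set(contiguous_skip_variants())
    )


@dataclass(frozen=True)
class HyperParamGrid:
    epochs: tuple[int, ...]
    batch_sizes: tuple[int, ...]
    optimizers: tuple[str, ...]
    loss_functions: tuple[str, ...]
    learning_rates: tuple[float, ...]
    dropouts: tuple[float, ...]

    def __post_init__(self) -> None:
        for f in fields(self):
            vals = getattr(self, f.name)
            object.__setattr__(self, f.name, tuple(vals))
            if not vals:
                raise ValueError(f"grid dimension {f.name} is empty")
        if any(e <= 0 for e in self.epochs) or any(b <= 0 for b in self.batch_sizes):
            raise ValueError("epochs and batch sizes must be positive")
        if any(lr <= 0 for lr in self.learning_rates):
            raise ValueError("learning rates must be positive")

    def size(self) -> int:
        return (
            len(self.epochs)
            * len(self.batch_sizes)
            * len(self.optimizers)
            * len(self.loss_functions)
            * len(self.learning_rates)
            * len(self.dropouts)
        )


def table8_grid() -> HyperParamGrid:
    """The published CNN fine-tuning search space (1152 configurations)."""
    return HyperParamGrid(
        epochs=(25, 50, 75, 100),
        batch_sizes=(8, 16, 32),
        optimizers=("SGD", "Adam", "Adamax", "RMSProp"),
        loss_functions=("categorical_crossentropy", "kullback_leibler_divergence"),
        learning_rates=(0.01, 0.001, 0.0001),
        dropouts=(0.5, 0.6, 0.7, 0.8),
    )


def enumerate_grid(grid: HyperParamGrid) -> list[dict[str, Any]]:
    """Full Cartesian product, row-major over the field order."""
    keys = ("epochs", "batch_size", "optimizer", "loss", "learning_rate", "dropout")
    product = itertools.product(
        grid.epochs,
        grid.batch_sizes,
        grid.optimizers,
        grid.loss_functions,
        grid.learning_rates,
        grid.dropouts,
    )
    return [dict(zip(keys, combo)) for combo in product]


@dataclass(frozen=True)
class CandidateRecord:
    model_name: str
    config: Any = None  # HeadArchitecture or a grid point
    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    auc: float | None = None

    def __post_init__(self) -> None:
        for name in ("accuracy", "sensitivity", "specificity", "auc"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def select_top_candidate(records: Sequence[CandidateRecord]) -> CandidateRecord:
    """Highest accuracy; ties broken by higher AUC, then smaller head
    parameter count, then earlier (canonical) input order — deterministic.
    """
    scored = [r for r in records if r.accuracy is not None]
    if not scored:
        raise ValueError("no records with accuracy")

    def params(r: CandidateRecord) -> int:
        return r.config.param_count if isinstance(r.config, HeadArchitecture) else 0

    best = scored[0]
    for r in scored[1:]:
        key_r = (r.accuracy, r.auc if r.auc is not None else -1.0, -params(r))
        key_b = (best.accuracy, best.auc if best.auc is not None else -1.0, -params(best))
        if key_r > key_b:
            best = r
    return best


def architectures_to_json(archs: Sequence[HeadArchitecture], path) -> None:
    with open(path, "w") as fh:
        json.dump([list(a.widths) for a in archs], fh)
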