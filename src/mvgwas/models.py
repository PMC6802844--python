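"""Enumeration of multivariate association models.

Each SNP-level model assigns every phenotype to one of three categories:

* ``0`` — Unassociated (U): no connection with the genotype,
* ``1`` — Directly associated (D): a direct genotype effect,
* ``2`` — Indirectly associated (I): associated with the genotype only
  through the directly associated phenotypes, so the association vanishes
  after conditioning on them.

For ``d`` phenotypes there are ``3**d`` such assignments; the all-zeros
assignment is the global null. The exhaustive enumeration is the method,
which keeps it tractable only for moderate ``d`` (about 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

UNASSOCIATED = 0
DIRECT = 1
INDIRECT = 2

#: Hard ceiling on the phenotype count for exhaustive enumeration.
DEFAULT_MAX_D = 10


@dataclass(frozen=True)
class ModelPartition:
    """One assignment of phenotypes to the U/D/I categories.

    ``codes`` holds one integer in {0, 1, 2} per phenotype; rendering with
    `code_string` produces the "1 0 2"-style labels used in reports.
    """

    codes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.codes) < 1:
            raise ValueError("a model partition needs at least one phenotype")
        if any(c not in (0, 1, 2) for c in self.codes):
            raise ValueError(f"invalid category codes {self.codes!r}; expected 0, 1 or 2")

    @property
    def d(self) -> int:
        return len(self.codes)

    @property
    def is_null(self) -> bool:
        return all(c == UNASSOCIATED for c in self.codes)

    def partition_sets(self) -> tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...]]:
        """Return (U, D, I) as disjoint tuples of 0-based phenotype indices."""
        u = tuple(i for i, c in enumerate(self.codes) if c == UNASSOCIATED)
        d = tuple(i for i, c in enumerate(self.codes) if c == DIRECT)
        i_ = tuple(i for i, c in enumerate(self.codes) if c == INDIRECT)
        return u, d, i_

    def code_string(self) -> str:
        return " ".join(str(c) for c in self.codes)

    @classmethod
    def from_code_string(cls, s: str) -> "ModelPartition":
        return cls(tuple(int(tok) for tok in s.split()))


@dataclass(frozen=True)
class ModelSpace:
    """All ``3**d`` model partitions in canonical order.

    Canonical order is base-3 ascending with phenotype 0 as the most
    significant digit, so the null model (all zeros) is always first.
    """

    d: int
    models: tuple[ModelPartition, ...] = field(repr=False)
    null_index: int = 0

    @property
    def size(self) -> int:
        return len(self.models)

    @property
    def codes_matrix(self) -> np.ndarray:
        """(3^d, d) integer matrix of category codes, canonical order."""
        return np.array([m.codes for m in self.models], dtype=np.int8)

    def index_of(self, model: ModelPartition) -> int:
        idx = 0
        for c in model.codes:
            idx = idx * 3 + c
        return idx

    def code_strings(self) -> list[str]:
        return [m.code_string() for m in self.models]


def enumerate_models(d: int, max_d: int = DEFAULT_MAX_D) -> ModelSpace:
    """Enumerate all ``3**d`` U/D/I assignments for ``d`` phenotypes.

    Parameters
    ----------
    d : int
        Number of phenotypes (``>= 1``).
    max_d : int
        Capacity guard; the exhaustive model space grows as ``3**d``.

    Raises
    ------
    ValueError
        If ``d < 1``, or if ``d > max_d`` (the error names ``3**d`` so the
        caller can judge the cost of raising the bound).
    """
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    if d > max_d:
        raise ValueError(
            f"d={d} implies {3 ** d} models, above the configured bound of "
            f"{3 ** max_d} (max_d={max_d}); raise max_d explicitly to proceed"
        )
    digits = np.arange(3 ** d)
    models = []
    for value in digits:
        codes = []
        v = int(value)
        for _ in range(d):
            codes.append(v % 3)
            v //= 3
        models.append(ModelPartition(tuple(reversed(codes))))
    return ModelSpace(d=d, models=tuple(models), null_index=0)


def partition_sets(model: ModelPartition) -> tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...]]:
    """Decode a partition into its (U, D, I) index sets (0-based)."""
    return model.partition_sets()
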