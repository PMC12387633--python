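"""Core data containers for multiblock studies.

A *block* is one samples x variables intensity matrix coming from a single
analytical platform (LC-HRMS2 features, GC-MS features, 1H NMR bins, ...).
All blocks of a study share the same samples in the same order; variables are
platform specific.  The :class:`BlockMatrix` carries, next to the values, a
monotone chain of *state flags* recording which preprocessing steps have been
applied, so that out-of-order pipelines fail loudly instead of silently
producing wrong scalings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Preprocessing states in their mandatory order along the chain.
STATE_ORDER = ("raw", "pqn", "logged", "centered", "scaled", "block_scaled")


class PipelineStateError(RuntimeError):
    """Raised when a preprocessing step is applied out of order."""


@dataclass
class BlockMatrix:
    """One samples x variables matrix with block identity and state.

    Parameters
    ----------
    block_id:
        Block label, conventionally ``"X1"``–``"X4"`` but any string is
        accepted.
    samples, variables:
        Row and column identifiers.
    values:
        Float matrix of shape ``(len(samples), len(variables))``.
    state:
        Tuple of flags from :data:`STATE_ORDER` already applied, in order.
    params:
        Fitted preprocessing parameters (PQN factors, column means, column
        scale divisors, block divisor) keyed by step name.
    """

    block_id: str
    samples: list[str]
    variables: list[str]
    values: np.ndarray
    state: tuple[str, ...] = ("raw",)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.variables)):
            raise ValueError(
                f"block {self.block_id}: values shape {self.values.shape} does not "
                f"match {len(self.samples)} samples x {len(self.variables)} variables"
            )
        unknown = [s for s in self.state if s not in STATE_ORDER]
        if unknown:
            raise ValueError(f"unknown state flags: {unknown}")

    # -- state bookkeeping -------------------------------------------------
    def has_state(self, flag: str) -> bool:
        return flag in self.state

    def require_state(self, *flags: str) -> None:
        """Raise :class:`PipelineStateError` unless all ``flags`` are set."""
        missing = [f for f in flags if f not in self.state]
        if missing:
            raise PipelineStateError(
                f"block {self.block_id}: step requires state {missing} but the "
                f"block is only {list(self.state)}; preprocessing must follow "
                f"the order {STATE_ORDER}"
            )

    def forbid_state(self, *flags: str) -> None:
        present = [f for f in flags if f in self.state]
        if present:
            raise PipelineStateError(
                f"block {self.block_id}: step must come before {present}, "
                f"but those states are already set"
            )

    def with_values(self, values: np.ndarray, add_state: str | None = None,
                    **new_params) -> "BlockMatrix":
        """Return a copy with new values, an optional extra state flag and
        extra stored parameters.  State flags stay monotone along the chain."""
        state = self.state
        if add_state is not None:
            if add_state not in STATE_ORDER:
                raise ValueError(f"unknown state flag {add_state!r}")
            if add_state not in state:
                state = tuple(s for s in STATE_ORDER
                              if s in state or s == add_state)
        params = dict(self.params)
        params.update(new_params)
        return BlockMatrix(self.block_id, list(self.samples),
                           list(self.variables), np.array(values, dtype=float),
                           state=state, params=params)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.samples, name="sample"),
                            columns=self.variables)

    def to_csv(self, path) -> None:
        """Write as CSV: header row of variable ids, first column sample id."""
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, block_id: str,
                 state: tuple[str, ...] = ("raw",)) -> "BlockMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(block_id, [str(s) for s in df.index],
                   [str(v) for v in df.columns], df.to_numpy(dtype=float),
                   state=state)

    def subset_samples(self, idx: np.ndarray) -> "BlockMatrix":
        """Row subset (for cross-validation folds); keeps state and params."""
        idx = np.asarray(idx)
        return BlockMatrix(self.block_id,
                           [self.samples[i] for i in idx],
                           list(self.variables), self.values[idx],
                           state=self.state, params=dict(self.params))


@dataclass
class StudyDesign:
    """Sample-to-condition assignment for a multi-group study."""

    samples: list[str]
    conditions: list[str]
    group_order: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.conditions):
            raise ValueError("samples and conditions must have equal length")
        if self.group_order is None:
            seen: dict[str, None] = {}
            for c in self.conditions:
                seen.setdefault(c, None)
            self.group_order = list(seen)
        missing = set(self.conditions) - set(self.group_order)
        if missing:
            raise ValueError(f"conditions {missing} absent from group_order")

    @property
    def groups(self) -> list[str]:
        return list(self.group_order)

    def group_indices(self, group: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.conditions) if c == group])

    def response_matrix(self) -> "ResponseMatrix":
        return ResponseMatrix.from_design(self)

    def subset(self, idx: np.ndarray) -> "StudyDesign":
        idx = np.asarray(idx)
        return StudyDesign([self.samples[i] for i in idx],
                           [self.conditions[i] for i in idx],
                           group_order=list(self.group_order))

    def to_csv(self, path) -> None:
        pd.DataFrame({"sample": self.samples,
                      "condition": self.conditions}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StudyDesign":
        df = pd.read_csv(path)
        return cls([str(s) for s in df["sample"]],
                   [str(c) for c in df["condition"]])


@dataclass
class ResponseMatrix:
    """One-hot dummy coding Y of the group membership (n samples x g groups).

    Every row sums to one and every group column has at least one sample;
    all four conditions are treated symmetrically (no reference-cell drop).
    """

    Y: np.ndarray
    groups: list[str]

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2 or self.Y.shape[1] != len(self.groups):
            raise ValueError("Y shape does not match group labels")
        if not np.allclose(self.Y.sum(axis=1), 1.0):
            raise ValueError("each row of Y must sum to 1 (one-hot coding)")
        if np.any(self.Y.sum(axis=0) < 1):
            raise ValueError("every group needs at least one sample")

    @classmethod
    def from_design(cls, design: StudyDesign) -> "ResponseMatrix":
        groups = design.groups
        Y = np.zeros((len(design.samples), len(groups)))
        for i, c in enumerate(design.conditions):
            Y[i, groups.index(c)] = 1.0
        return cls(Y, groups)

    @property
    def labels(self) -> np.ndarray:
        """Integer class labels (argmax of the one-hot rows)."""
        return np.argmax(self.Y, axis=1)


def check_aligned(blocks: list[BlockMatrix]) -> None:
    """Assert all blocks share sample ids in identical order."""
    if not blocks:
        raise ValueError("no blocks supplied")
    ref = blocks[0].samples
    for b in blocks[1:]:
        if b.samples != ref:
            raise ValueError(
                f"sample mismatch between blocks {blocks[0].block_id} and "
                f"{b.block_id}")
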