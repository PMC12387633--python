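"""Normalisation, transformation and scaling chain for multiblock studies.

The chain applied to each block, in order:

1. **PQN** — probabilistic quotient normalisation: each sample row is divided
   by the median of its elementwise ratios to a reference spectrum (default:
   the median spectrum over samples), removing per-sample dilution and
   total-amount effects.
2. **zero replacement + log** (MS blocks X1–X3 only) — exact zeros are
   replaced with a fixed positive intensity, then the block is
   log-transformed.  The NMR block is left on its native intensity scale.
3. **centering + column scaling** — mean centering followed by Pareto scaling
   (divide by the square root of the column SD) for the LC-HRMS2 block and
   unit-variance scaling for the GC-MS and NMR blocks.
4. **block scaling** — the whole block is divided by one scalar so its total
   column variance is 1, preventing wide blocks (8800 NMR bins) from
   swamping narrow ones (26 GC-MS features) in the multiblock fit.

`bin_spectrum` turns an aligned 1D NMR spectrum on a continuous ppm axis
into the fixed-width bin vector that constitutes the NMR block, with solvent
regions (residual water and methanol) masked out.

A :class:`StudyPreprocessor` fits the whole chain on training samples and
replays it, with frozen parameters, on held-out samples — the leakage-free
form required inside cross-validation folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .blocks import BlockMatrix

#: MS feature blocks that receive zero replacement + log transform.
LOG_BLOCKS = ("X1", "X2", "X3")

DEFAULT_SCALING = {"X1": "pareto", "X2": "uv", "X3": "uv", "X4": "uv"}


@dataclass
class PreprocessParams:
    """Tunable knobs of the preprocessing chain.

    zero_replacement
        Intensity substituted for exact zeros in the MS blocks before the
        log transform; must be positive.
    log_base
        Base of the logarithm applied to MS blocks.  Any base only rescales
        columns (absorbed by unit-variance scaling) but matters for the
        Pareto-scaled LC-HRMS2 block.
    scaling
        Per-block column scaling method: ``pareto``, ``uv`` or ``none``.
    ddof
        Delta degrees of freedom of the SD convention (1 = sample SD).
    """

    zero_replacement: float = 1000.0
    log_base: float = 10.0
    scaling: dict = field(default_factory=lambda: dict(DEFAULT_SCALING))
    ddof: int = 1

    def __post_init__(self) -> None:
        if self.zero_replacement <= 0:
            raise ValueError("zero_replacement must be > 0")
        if self.log_base <= 0 or self.log_base == 1:
            raise ValueError("log_base must be positive and != 1")
        for blk, meth in self.scaling.items():
            if meth not in ("pareto", "uv", "none"):
                raise ValueError(f"scaling[{blk!r}] must be pareto|uv|none")

    def scaling_for(self, block_id: str) -> str:
        return self.scaling.get(block_id, "uv")


@dataclass
class SpectrumBinningSpec:
    """Uniform binning of a 1D NMR spectrum over a chemical-shift range.

    The default reproduces the study layout: bins of 0.001 ppm between 0.2
    and 9.0 ppm (8800 columns) with the residual-water (4.74–4.94 ppm) and
    methanol (3.26–3.36 ppm) regions excluded.  ``mode="mask"`` zeroes the
    excluded bins but keeps them as columns; ``mode="drop"`` removes them.
    """

    ppm_min: float = 0.2
    ppm_max: float = 9.0
    width: float = 0.001
    excluded: tuple = ((4.74, 4.94), (3.26, 3.36))
    mode: str = "mask"

    def __post_init__(self) -> None:
        if self.ppm_min >= self.ppm_max:
            raise ValueError("ppm range bounds must be ordered")
        if self.width <= 0:
            raise ValueError("bin width must be > 0")
        for lo, hi in self.excluded:
            if lo >= hi or lo < self.ppm_min or hi > self.ppm_max:
                raise ValueError("excluded regions must lie inside the range")
        if self.mode not in ("mask", "drop"):
            raise ValueError("mode must be 'mask' or 'drop'")

    @property
    def n_bins(self) -> int:
        return int(round((self.ppm_max - self.ppm_min) / self.width))

    def edges(self) -> np.ndarray:
        return self.ppm_min + self.width * np.arange(self.n_bins + 1)

    def centers(self) -> np.ndarray:
        e = self.edges()
        return 0.5 * (e[:-1] + e[1:])

    def masked_bins(self) -> np.ndarray:
        """Boolean vector: True where a bin overlaps an excluded region."""
        e = self.edges()
        left, right = e[:-1], e[1:]
        mask = np.zeros(self.n_bins, dtype=bool)
        eps = 1e-6 * self.width   # edge-touching bins do not overlap
        for lo, hi in self.excluded:
            mask |= (left < hi - eps) & (right > lo + eps)
        return mask


# ---------------------------------------------------------------------------
# individual chain steps
# ---------------------------------------------------------------------------

def pqn_factors(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Per-row PQN dilution factors against ``reference``.

    The factor of row i is the median of ``row_i[j] / reference[j]`` over
    variables j positive in both the row and the reference, so injected
    zeros (missing features) do not poison the median.
    """
    values = np.asarray(values, dtype=float)
    reference = np.asarray(reference, dtype=float)
    factors = np.empty(values.shape[0])
    ref_pos = reference > 0
    for i, row in enumerate(values):
        both = ref_pos & (row > 0)
        if not both.any():
            raise ValueError(
                f"row {i} has no positive overlap with the PQN reference")
        factors[i] = np.median(row[both] / reference[both])
    return factors


def pqn_normalize(X: BlockMatrix, reference: np.ndarray | None = None
                  ) -> tuple[BlockMatrix, np.ndarray]:
    """Probabilistic quotient normalisation of every sample row.

    Parameters
    ----------
    X:
        Raw block with non-negative entries.
    reference:
        Reference spectrum; defaults to the columnwise median over samples.

    Returns
    -------
    (normalized block, per-sample factors)
    """
    X.require_state("raw")
    X.forbid_state("pqn", "logged", "centered")
    if np.any(X.values < 0):
        raise ValueError("PQN expects non-negative intensities")
    if reference is None:
        reference = np.median(X.values, axis=0)
    factors = pqn_factors(X.values, reference)
    out = X.values / factors[:, None]
    return X.with_values(out, add_state="pqn",
                         pqn_factors=factors, pqn_reference=np.asarray(reference)), factors


def replace_zeros_log(X: BlockMatrix, params: PreprocessParams | None = None
                      ) -> BlockMatrix:
    """Replace exact zeros with a fixed intensity, then log-transform.

    Applies only to the MS blocks (X1–X3); zeros from missing features are
    replaced with ``params.zero_replacement`` (default 1000) so the log is
    defined, then the block is taken to ``log_base`` elementwise.
    """
    params = params or PreprocessParams()
    if X.block_id not in LOG_BLOCKS:
        raise ValueError(
            f"log transform applies to blocks {LOG_BLOCKS}, not {X.block_id}")
    X.forbid_state("logged", "centered", "scaled")
    if np.any(X.values < 0):
        raise ValueError("negative entries cannot be log-transformed")
    vals = np.where(X.values == 0, params.zero_replacement, X.values)
    vals = np.log(vals) / np.log(params.log_base)
    return X.with_values(vals, add_state="logged",
                         zero_replacement=params.zero_replacement,
                         log_base=params.log_base)


def _column_divisors(values: np.ndarray, method: str, ddof: int) -> np.ndarray:
    sd = np.std(values, axis=0, ddof=ddof)
    if method == "none":
        return np.ones(values.shape[1])
    div = sd if method == "uv" else np.sqrt(sd)
    # constant columns: centered to zero, left undivided
    div[sd == 0] = 1.0
    return div


def center_scale(X: BlockMatrix, method: str | None = None,
                 params: PreprocessParams | None = None) -> BlockMatrix:
    """Mean-center columns, then scale: ``uv`` divides by the column SD,
    ``pareto`` by its square root.  Constant columns become all-zero."""
    params = params or PreprocessParams()
    if method is None:
        method = params.scaling_for(X.block_id)
    if method not in ("pareto", "uv", "none"):
        raise ValueError("method must be pareto|uv|none")
    X.forbid_state("centered", "scaled", "block_scaled")
    means = X.values.mean(axis=0)
    centered = X.values - means
    div = _column_divisors(X.values, method, params.ddof)
    out = X.with_values(centered / div, add_state="centered",
                        column_means=means, column_divisors=div,
                        scaling_method=method)
    return out.with_values(out.values, add_state="scaled")


def block_scale(X: BlockMatrix, ddof: int = 1) -> BlockMatrix:
    """Scale the whole block so its total column variance is 1.

    The divisor is the square root of the sum of column variances, making
    blocks of very different width comparable in the multiblock model.
    """
    X.require_state("centered", "scaled")
    total_var = np.sum(np.var(X.values, axis=0, ddof=ddof))
    if total_var == 0:
        raise ValueError(f"block {X.block_id} is all zero; cannot block-scale")
    divisor = float(np.sqrt(total_var))
    return X.with_values(X.values / divisor, add_state="block_scaled",
                         block_divisor=divisor)


def bin_spectrum(ppm_axis: np.ndarray, intensities: np.ndarray,
                 spec: SpectrumBinningSpec | None = None) -> np.ndarray:
    """Integrate a 1D spectrum into uniform chemical-shift bins.

    Each bin holds the summed intensity of the axis points falling in
    ``[left, right)``.  In ``mask`` mode bins overlapping an excluded solvent
    region are set to 0 but kept as columns; in ``drop`` mode they are
    removed from the output.
    """
    spec = spec or SpectrumBinningSpec()
    ppm_axis = np.asarray(ppm_axis, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if ppm_axis.shape != intensities.shape:
        raise ValueError("ppm axis and intensities must have the same length")
    d = np.diff(ppm_axis)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("ppm axis must be strictly monotone")
    in_range = (ppm_axis >= spec.ppm_min) & (ppm_axis < spec.ppm_max)
    if not in_range.any():
        raise ValueError("spectrum has no overlap with the binning range")
    idx = np.floor((ppm_axis[in_range] - spec.ppm_min) / spec.width).astype(int)
    idx = np.clip(idx, 0, spec.n_bins - 1)
    bins = np.bincount(idx, weights=intensities[in_range], minlength=spec.n_bins)
    mask = spec.masked_bins()
    if spec.mode == "mask":
        bins[mask] = 0.0
        return bins
    return bins[~mask]


# ---------------------------------------------------------------------------
# fitted chain for train/apply reuse
# ---------------------------------------------------------------------------

@dataclass
class _BlockPreprocessor:
    block_id: str
    pqn_reference: np.ndarray
    scaling_method: str
    column_means: np.ndarray
    column_divisors: np.ndarray
    block_divisor: float
    logged: bool
    zero_replacement: float
    log_base: float

    def apply(self, X: BlockMatrix) -> BlockMatrix:
        """Replay the fitted chain on new samples (no refitting)."""
        if X.variables and len(X.variables) != len(self.column_means):
            raise ValueError(f"variable mismatch in block {self.block_id}")
        factors = pqn_factors(X.values, self.pqn_reference)
        vals = X.values / factors[:, None]
        if self.logged:
            vals = np.where(vals == 0, self.zero_replacement, vals)
            vals = np.log(vals) / np.log(self.log_base)
        vals = (vals - self.column_means) / self.column_divisors
        vals = vals / self.block_divisor
        return BlockMatrix(X.block_id, list(X.samples), list(X.variables),
                           vals, state=tuple(s for s in
                                             ("raw", "pqn", "logged", "centered",
                                              "scaled", "block_scaled")
                                             if s != "logged" or self.logged),
                           params={"pqn_factors": factors,
                                   "block_divisor": self.block_divisor})


@dataclass
class StudyPreprocessor:
    """The full chain fitted on one set of samples, reusable on others.

    ``fit`` learns every data-dependent parameter (PQN reference spectrum,
    column means and divisors, block divisors) from the training rows only;
    ``apply`` replays them verbatim on held-out rows.  Serialisable to JSON
    so fold parameters can be audited.
    """

    params: PreprocessParams
    blocks: dict = field(default_factory=dict)

    @classmethod
    def fit(cls, raw_blocks: list[BlockMatrix],
            params: PreprocessParams | None = None
            ) -> tuple["StudyPreprocessor", list[BlockMatrix]]:
        params = params or PreprocessParams()
        pre = cls(params=params)
        out = []
        for raw in raw_blocks:
            x, _ = pqn_normalize(raw)
            logged = raw.block_id in LOG_BLOCKS
            if logged:
                x = replace_zeros_log(x, params)
            x = center_scale(x, params=params)
            x = block_scale(x, ddof=params.ddof)
            pre.blocks[raw.block_id] = _BlockPreprocessor(
                block_id=raw.block_id,
                pqn_reference=x.params["pqn_reference"],
                scaling_method=x.params["scaling_method"],
                column_means=x.params["column_means"],
                column_divisors=x.params["column_divisors"],
                block_divisor=x.params["block_divisor"],
                logged=logged,
                zero_replacement=params.zero_replacement,
                log_base=params.log_base)
            out.append(x)
        return pre, out

    def apply(self, raw_blocks: list[BlockMatrix]) -> list[BlockMatrix]:
        return [self.blocks[b.block_id].apply(b) for b in raw_blocks]

    def block_divisors(self) -> dict:
        return {bid: bp.block_divisor for bid, bp in self.blocks.items()}

    def to_json(self, path) -> None:
        payload = {"params": asdict(self.params), "blocks": {}}
        for bid, bp in self.blocks.items():
            payload["blocks"][bid] = {
                "pqn_reference": bp.pqn_reference.tolist(),
                "scaling_method": bp.scaling_method,
                "column_means": bp.column_means.tolist(),
                "column_divisors": bp.column_divisors.tolist(),
                "block_divisor": bp.block_divisor,
                "logged": bp.logged,
                "zero_replacement": bp.zero_replacement,
                "log_base": bp.log_base,
            }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "StudyPreprocessor":
        with open(path) as fh:
            payload = json.load(fh)
        pre = cls(params=PreprocessParams(**payload["params"]))
        for bid, d in payload["blocks"].items():
            pre.blocks[bid] = _BlockPreprocessor(
                block_id=bid,
                pqn_reference=np.asarray(d["pqn_reference"]),
                scaling_method=d["scaling_method"],
                column_means=np.asarray(d["column_means"]),
                column_divisors=np.asarray(d["column_divisors"]),
                block_divisor=d["block_divisor"],
                logged=d["logged"],
                zero_replacement=d["zero_replacement"],
                log_base=d["log_base"])
        return pre
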