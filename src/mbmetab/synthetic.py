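"""Seeded generator of four-block, four-condition surrogate studies.

The real study design is emulated end to end: four culture conditions
(CG, CPT, CPDMS, CP) with five replicates each, observed through four
analytical blocks — an LC-HRMS2 feature matrix (X1, 1049 variables), two
GC-MS feature matrices (X2, 26 and X3, 42 variables) and a 1H NMR bin
matrix (X4, 8800 bins over 9.0–0.2 ppm).

Group structure is *planted* along three contrasts:

* C1 — planktonic vs adherent (CP vs CG/CPT/CPDMS),
* C2 — glass vs the rest (CG vs CP/CPT/CPDMS),
* C3 — hard vs soft hydrophobic support (CPT vs CPDMS),

by shifting the log-scale group means of disjoint variable sets per block.
Effect sizes are expressed in multiples of the within-group SD, and their
signs are split between up- and down-regulated variables so that the
"increased-in" direction assignment downstream is exercised both ways.

MS intensities are log-normal with intensity-dependent dropout (exact
zeros, mimicking detection limits); the NMR block is synthesised as
Lorentzian peaks on a continuous ppm axis and then passed through the same
binning routine used for real spectra.  A per-sample multiplicative
dilution factor, shared by all blocks, creates exactly the nuisance that
probabilistic quotient normalisation is designed to remove.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .blocks import BlockMatrix, StudyDesign
from .preprocessing import SpectrumBinningSpec, bin_spectrum

DEFAULT_GROUPS = ("CG", "CPT", "CPDMS", "CP")
DEFAULT_BLOCK_DIMS = {"X1": 1049, "X2": 26, "X3": 42, "X4": 8800}

#: Contrast name -> (positive-side groups, negative-side groups).  One-sided
#: contrasts shift only the positive side by the full effect; the two-sided
#: CPT-vs-CPDMS contrast splits the effect half up / half down so both
#: hydrophobic-support groups carry an active signature, while the planted
#: group-mean difference stays equal to the configured effect size.
CONTRASTS = {"C1": (("CP",), ()),
             "C2": (("CG",), ()),
             "C3": (("CPT",), ("CPDMS",))}
#: Contrast name -> human-readable definition.
CONTRAST_DEFS = {
    "C1": "CP vs {CG, CPT, CPDMS}",
    "C2": "CG vs {CP, CPT, CPDMS}",
    "C3": "CPT vs CPDMS",
}

NMR_PPM_RANGE = (0.2, 9.0)


def nmr_binning_spec(n_bins: int) -> SpectrumBinningSpec:
    """Binning spec whose uniform width yields exactly ``n_bins`` columns
    over the 0.2–9.0 ppm window (default 8800 -> 0.001 ppm)."""
    lo, hi = NMR_PPM_RANGE
    return SpectrumBinningSpec(ppm_min=lo, ppm_max=hi,
                               width=(hi - lo) / n_bins, mode="mask")


def default_planted_sets(block_dims: dict[str, int] | None = None,
                         effect_size: float = 2.0,
                         n_contrast23: int = 20) -> dict:
    """Planted variable sets per contrast per block, with signed effects.

    Contrast 1 (planktonic vs adherent) receives at least 20 variables per
    block whenever the block is wide enough; contrasts 2 and 3 receive up
    to 20 each from the remaining variables.  Signs alternate so roughly
    half the plants go up and half go down.  NMR plants are placed on bins
    well away from the masked solvent regions and the spectrum edges.
    """
    dims = dict(DEFAULT_BLOCK_DIMS if block_dims is None else block_dims)
    planted: dict = {c: {} for c in CONTRASTS}
    for bid, p in dims.items():
        n1 = 20 if p >= 26 else max(2, p // 3)
        n23 = min(n_contrast23, max(1, (p - n1) // 2))
        if bid == "X4":
            spec = nmr_binning_spec(p)
            bad = spec.masked_bins().astype(float)
            # keep plants >= 5 bins away from masked regions and edges
            pad = np.convolve(bad, np.ones(11), mode="same") > 0
            pad[: max(5, p // 100)] = True
            pad[-max(5, p // 100):] = True
            cand = np.flatnonzero(~pad)
            total = n1 + 2 * n23
            if len(cand) < 3 * total:
                raise ValueError("X4 too small for the requested plants")
            picks = cand[np.linspace(0, len(cand) - 1, total).astype(int)]
            idx1 = picks[:n1]
            idx2 = picks[n1:n1 + n23]
            idx3 = picks[n1 + n23:]
        else:
            idx1 = np.arange(n1)
            idx2 = np.arange(n1, n1 + n23)
            idx3 = np.arange(n1 + n23, n1 + 2 * n23)
        for c, idx in zip(("C1", "C2", "C3"), (idx1, idx2, idx3)):
            planted[c][bid] = [(int(j), effect_size * (1 if k % 2 == 0 else -1))
                               for k, j in enumerate(idx)]
    return planted


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic four-block study.

    Effect sizes inside ``planted_sets`` are in multiples of ``noise_sd``,
    the within-group SD on the log10 scale.  ``dilution_range`` bounds the
    per-sample multiplicative factor; ``zero_rate`` is the expected
    fraction of exact zeros injected into the MS blocks (X1–X3).
    """

    n_per_group: int = 5
    groups: tuple = DEFAULT_GROUPS
    block_dims: dict = field(default_factory=lambda: dict(DEFAULT_BLOCK_DIMS))
    planted_sets: dict | None = None
    effect_size: float = 2.0
    dilution_range: tuple = (0.5, 2.0)
    zero_rate: float = 0.10
    noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if any(d < 1 for d in self.block_dims.values()):
            raise ValueError("all block dimensions must be >= 1")
        if not (0 <= self.zero_rate < 1):
            raise ValueError("zero_rate must be in [0, 1)")
        lo, hi = self.dilution_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("dilution_range must be a positive interval")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.planted_sets is None:
            self.planted_sets = default_planted_sets(self.block_dims,
                                                     self.effect_size)
        self._validate_plants()

    def _validate_plants(self) -> None:
        for bid, p in self.block_dims.items():
            seen: set[int] = set()
            for c in self.planted_sets:
                for j, _ in self.planted_sets[c].get(bid, []):
                    if not (0 <= j < p):
                        raise ValueError(
                            f"planted index {j} out of range for block {bid} "
                            f"({p} variables)")
                    if j in seen:
                        raise ValueError(
                            f"planted sets overlap across contrasts in block "
                            f"{bid} at index {j}")
                    seen.add(j)


@dataclass
class GroundTruth:
    """What was planted: variable ids per contrast per block, the contrast
    definitions, and the per-sample dilution factors."""

    planted: dict            # contrast -> block -> list[(variable_id, effect)]
    contrast_defs: dict
    dilution_factors: np.ndarray

    def planted_ids(self, contrast: str, block_id: str) -> list[str]:
        return [v for v, _ in self.planted[contrast].get(block_id, [])]

    def to_json(self, path) -> None:
        payload = {"planted": self.planted,
                   "contrast_defs": self.contrast_defs,
                   "dilution_factors": self.dilution_factors.tolist()}
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)


def _effect_matrix(cfg: SyntheticConfig, bid: str, conditions: list[str]
                   ) -> np.ndarray:
    """Additive log10 group-effect matrix (n x p) before noise."""
    n, p = len(conditions), cfg.block_dims[bid]
    eff = np.zeros((n, p))
    for c, (pos_groups, neg_groups) in CONTRASTS.items():
        pos = [i for i, g in enumerate(conditions) if g in pos_groups]
        neg = [i for i, g in enumerate(conditions) if g in neg_groups]
        # split the effect across both sides when the contrast is two-sided
        share = 0.5 if neg else 1.0
        for j, e in cfg.planted_sets[c].get(bid, []):
            eff[np.ix_(pos, [j])] += share * e * cfg.noise_sd
            if neg:
                eff[np.ix_(neg, [j])] -= share * e * cfg.noise_sd
    return eff


def _inject_zeros(values: np.ndarray, rate: float, rng: np.random.Generator
                  ) -> np.ndarray:
    """Intensity-dependent dropout: probability decreases linearly from
    2*rate (lowest intensity) to 0 (highest), so low-abundance features go
    missing preferentially while the expected zero fraction stays ~rate."""
    if rate == 0:
        return values
    flat = values.ravel()
    order = np.argsort(np.argsort(flat))          # ranks, 0 = smallest
    p_drop = np.clip(2.0 * rate * (1.0 - order / (flat.size - 1 or 1)), 0, 1)
    drop = rng.random(flat.size) < p_drop
    out = flat.copy()
    out[drop] = 0.0
    return out.reshape(values.shape)


def _ms_block(cfg: SyntheticConfig, bid: str, conditions: list[str],
              rng: np.random.Generator) -> np.ndarray:
    n, p = len(conditions), cfg.block_dims[bid]
    baseline = rng.normal(5.0, 0.8, size=p)       # log10 intensity levels
    logv = baseline + _effect_matrix(cfg, bid, conditions) \
        + rng.normal(0.0, cfg.noise_sd, size=(n, p))
    return _inject_zeros(10.0 ** logv, cfg.zero_rate, rng)


def _nmr_block(cfg: SyntheticConfig, conditions: list[str],
               rng: np.random.Generator) -> tuple[np.ndarray, SpectrumBinningSpec]:
    """Per-sample Lorentzian peak spectra binned into the X4 matrix.

    Each planted bin hosts a dedicated peak centred on it; background peaks
    are scattered over the remaining unmasked bins.  Per-sample log10 peak
    amplitudes carry the group effects and within-group noise, so a planted
    bin's log intensity behaves like a planted MS feature.
    """
    n_bins = cfg.block_dims["X4"]
    spec = nmr_binning_spec(n_bins)
    centers = spec.centers()
    eff = _effect_matrix(cfg, "X4", conditions)
    planted_bins = sorted({j for c in cfg.planted_sets
                           for j, _ in cfg.planted_sets[c].get("X4", [])})
    # background peaks away from plants and solvent masks
    bad = spec.masked_bins().copy()
    for j in planted_bins:
        bad[max(0, j - 3): j + 4] = True
    free = np.flatnonzero(~bad)
    n_bg = min(60, len(free) // 4)
    bg_bins = rng.choice(free, size=n_bg, replace=False) if n_bg else np.array([], int)

    peak_bins = np.concatenate([np.asarray(planted_bins, int), bg_bins])
    n_peaks = len(peak_bins)
    base_amp = rng.normal(4.0, 0.5, size=n_peaks)        # log10 height
    gamma = spec.width * rng.uniform(0.4, 0.8, size=n_peaks)  # HWHM, ppm

    # fine axis at 1/8 bin width; each peak is evaluated on a +-2 bin
    # window, so peaks >= 3 bins apart cannot bleed into each other's bins
    # (plants and background are placed with at least that separation)
    step = spec.width / 8.0
    axis = np.arange(spec.ppm_min + step / 2, spec.ppm_max, step)
    n = len(conditions)
    X4 = np.empty((n, n_bins))
    win = int(round(2 * spec.width / step))
    pos_idx = np.clip(((centers[peak_bins] - axis[0]) / step).round().astype(int),
                      0, len(axis) - 1)
    for i in range(n):
        amp_log = base_amp + rng.normal(0.0, cfg.noise_sd, size=n_peaks)
        # planted peaks occupy the first len(planted_bins) slots
        for k, j in enumerate(planted_bins):
            amp_log[k] += eff[i, j]
        spectrum = np.zeros(len(axis))
        for k in range(n_peaks):
            c0 = pos_idx[k]
            lo, hi = max(0, c0 - win), min(len(axis), c0 + win + 1)
            x = axis[lo:hi] - centers[peak_bins[k]]
            spectrum[lo:hi] += (10.0 ** amp_log[k]) * gamma[k] ** 2 \
                / (x ** 2 + gamma[k] ** 2)
        X4[i] = bin_spectrum(axis, spectrum, spec)
    return X4, spec


def apply_dilution(X: BlockMatrix, factors: np.ndarray) -> BlockMatrix:
    """Multiply each sample row by its positive dilution factor."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (X.n_samples,):
        raise ValueError("one dilution factor per sample required")
    if np.any(factors <= 0):
        raise ValueError("dilution factors must be strictly positive")
    return X.with_values(X.values * factors[:, None])


def generate_study(config: SyntheticConfig | None = None
                   ) -> tuple[list[BlockMatrix], StudyDesign, GroundTruth]:
    """Generate one seeded study: four blocks, design table, ground truth.

    The global seed spawns one child seed stream per block plus one for the
    dilution factors (via ``numpy.random.SeedSequence.spawn``), so a block
    can be regenerated independently of the others.  Identical config and
    seed give bit-identical output.
    """
    cfg = config or SyntheticConfig()
    groups = list(cfg.groups)
    conditions = [g for g in groups for _ in range(cfg.n_per_group)]
    samples = [f"{g}_{r + 1}" for g in groups for r in range(cfg.n_per_group)]
    design = StudyDesign(samples, conditions, group_order=groups)

    children = np.random.SeedSequence(cfg.seed).spawn(len(cfg.block_dims) + 1)
    rngs = {bid: np.random.default_rng(s)
            for bid, s in zip(sorted(cfg.block_dims), children)}
    dil_rng = np.random.default_rng(children[-1])
    lo, hi = cfg.dilution_range
    factors = dil_rng.uniform(lo, hi, size=len(samples))

    blocks: list[BlockMatrix] = []
    var_ids: dict[str, list[str]] = {}
    for bid in ("X1", "X2", "X3", "X4"):
        if bid not in cfg.block_dims:
            continue
        if bid == "X4":
            vals, spec = _nmr_block(cfg, conditions, rngs[bid])
            ids = [f"ppm_{c:.4f}" for c in spec.centers()]
        else:
            vals = _ms_block(cfg, bid, conditions, rngs[bid])
            ids = [f"{bid}_mz_{j:04d}" for j in range(cfg.block_dims[bid])]
        var_ids[bid] = ids
        blk = BlockMatrix(bid, samples, ids, vals)
        blocks.append(apply_dilution(blk, factors))

    planted = {c: {bid: [(var_ids[bid][j], float(e)) for j, e in pairs]
                   for bid, pairs in cfg.planted_sets[c].items()
                   if bid in var_ids}
               for c in cfg.planted_sets}
    truth = GroundTruth(planted=planted, contrast_defs=dict(CONTRAST_DEFS),
                        dilution_factors=factors)
    return blocks, design, truth


def save_study(path_dir, blocks: list[BlockMatrix], design: StudyDesign,
               truth: GroundTruth) -> None:
    """Write blocks and design as CSV and the ground truth as JSON."""
    import os
    os.makedirs(path_dir, exist_ok=True)
    for b in blocks:
        b.to_csv(os.path.join(path_dir, f"{b.block_id}.csv"))
    design.to_csv(os.path.join(path_dir, "design.csv"))
    truth.to_json(os.path.join(path_dir, "ground_truth.json"))
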