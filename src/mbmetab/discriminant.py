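"""Discriminant-variable selection and biplot geometry.

A variable is *discriminant* on a component axis when the absolute value of
its block weight falls in the upper quarter of the range of absolute
weights of its block on that axis:

    threshold = min|w| + 0.75 * (max|w| - min|w|)

applied independently per block and per axis.  Each selected variable is
assigned an "increased-in" group set: the groups whose super-score
centroids on that axis share the sign of the variable's weight (variables
project towards the samples in which they are elevated).  For a
one-vs-rest component this yields either the single separated group or the
complementary coalition.

Biplot coordinates compensate the block-normalisation effects of the
multiblock fit: each block's unit-norm weight vector spreads its mass over
the block's variables (entries shrink like 1/sqrt(p_b)) while the block
divisor grows with block width, so multiplying a variable's weight by its
block divisor puts variables from a 26-column GC-MS block and an 8800-bin
NMR block on one comparable scale.  One uniform positive factor per panel
then normalises to a common display radius, preserving every variable's
angle to the component axes exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import BlockMatrix, StudyDesign
from .mbpls import MBPLSModel, fit_mbpls
from .preprocessing import PreprocessParams, StudyPreprocessor

AXIS_NAMES = ("T1", "T2", "T3", "T4", "T5", "T6")

#: a group joins the increased-in coalition only when its centroid exceeds
#: this fraction of the axis score SD (below it the group is neutral).
CENTROID_MIN_FRACTION = 0.1


@dataclass
class DiscriminantVariable:
    block_id: str
    variable_id: str
    variable_index: int
    axis: int                      # 0-based component index
    weight: float
    increased_in: tuple
    sign: int
    biplot: dict = field(default_factory=dict)   # panel -> (x, y)
    stable: bool | None = None

    @property
    def axis_name(self) -> str:
        return AXIS_NAMES[self.axis]


def selection_threshold(abs_weights: np.ndarray, rule: str = "range-quarter",
                        fraction: float = 0.75) -> float:
    """Cutoff on |w| for one block/axis weight vector.

    ``range-quarter`` (default, the upper quarter of the min–max spread),
    ``fraction-of-max`` (0.75·max|w|) and ``top-quarter-count`` (the top
    25% of variables by |w|) are supported.  A zero range selects every
    variable (degenerate inputs only).
    """
    aw = np.abs(np.asarray(abs_weights, float))
    if aw.size == 0:
        raise ValueError("empty weight vector")
    if rule == "range-quarter":
        return float(aw.min() + fraction * (aw.max() - aw.min()))
    if rule == "fraction-of-max":
        return float(fraction * aw.max())
    if rule == "top-quarter-count":
        k = max(1, math.ceil((1.0 - fraction) * aw.size))
        return float(np.sort(aw)[-k])
    raise ValueError(f"unknown selection rule {rule!r}")


def assign_direction(model: MBPLSModel, design: StudyDesign, axis: int,
                     weight_sign: int) -> tuple:
    """Increased-in group set for a variable with ``weight_sign`` on ``axis``.

    Groups whose score centroid shares the weight's sign and is at least
    ``CENTROID_MIN_FRACTION`` of the axis score SD join the coalition; if no
    group passes the size gate, the group most aligned with the weight is
    returned alone, so the set is never empty.
    """
    t = model.super_scores[:, axis]
    sd = t.std(ddof=1)
    if sd == 0 or weight_sign == 0:
        raise ValueError("degenerate axis or zero weight")
    cond = np.asarray(design.conditions)
    centroids = {g: t[cond == g].mean() for g in design.groups}
    if all(c == 0 for c in centroids.values()):
        raise ValueError(f"all group centroids are zero on axis {axis + 1}")
    chosen = [g for g, c in centroids.items()
              if np.sign(c) == weight_sign
              and abs(c) > CENTROID_MIN_FRACTION * sd]
    if not chosen:
        chosen = [max(centroids, key=lambda g: weight_sign * centroids[g])]
    return tuple(g for g in design.groups if g in chosen)


def select_discriminant(model: MBPLSModel, design: StudyDesign,
                        axes: tuple = (0, 1, 2), rule: str = "range-quarter",
                        fraction: float = 0.75) -> list[DiscriminantVariable]:
    """Upper-quarter discriminant variables per block per axis, with their
    increased-in group assignment.  Selection is invariant to negating any
    weight vector (the rule acts on |w|)."""
    out: list[DiscriminantVariable] = []
    for axis in axes:
        if axis >= model.n_components:
            raise ValueError(f"axis {axis + 1} beyond fitted components")
        for bid in model.block_ids:
            w = model.block_weights[bid][:, axis]
            thr = selection_threshold(np.abs(w), rule, fraction)
            for j in np.flatnonzero(np.abs(w) >= thr):
                s = int(np.sign(w[j])) or 1
                out.append(DiscriminantVariable(
                    block_id=bid,
                    variable_id=str(model.variables[bid][j]),
                    variable_index=int(j), axis=axis, weight=float(w[j]),
                    increased_in=assign_direction(model, design, axis, s),
                    sign=s))
    return out


def biplot_coordinates(model: MBPLSModel,
                       selected: list[DiscriminantVariable] | None = None,
                       panels: tuple = ((0, 1), (1, 2)),
                       display_radius: float = 1.0
                       ) -> dict[str, pd.DataFrame]:
    """Angle-preserving 2-D coordinates for score/loading biplot panels.

    For each panel (pair of component axes): every selected variable's
    weight pair is multiplied by its block's divisor (undoing the width
    dependence the block scaling introduced), then all variables share one
    positive factor normalising the largest radius to ``display_radius``;
    sample scores are scaled by their own uniform factor.  Uniform scaling
    preserves each point's angle to the component axes exactly.
    """
    out: dict[str, pd.DataFrame] = {}
    if not panels:
        return out
    if model.n_components < max(max(p) for p in panels) + 1:
        raise ValueError("model has fewer components than the panels require")
    if selected is None:
        selected = []
    for a1, a2 in panels:
        name = f"{AXIS_NAMES[a1]}-{AXIS_NAMES[a2]}"
        coords = np.array(
            [model.block_weights[v.block_id][v.variable_index, [a1, a2]]
             * model.block_divisors.get(v.block_id, 1.0) for v in selected]
        ).reshape(len(selected), 2)
        if len(selected):
            radius = np.linalg.norm(coords, axis=1).max()
            coords = coords * (display_radius / radius if radius > 0 else 1.0)
            for v, (x, y) in zip(selected, coords):
                v.biplot[name] = (float(x), float(y))
        var_df = pd.DataFrame(
            {"block": [v.block_id for v in selected],
             "variable_id": [v.variable_id for v in selected],
             AXIS_NAMES[a1]: coords[:, 0] if len(selected) else [],
             AXIS_NAMES[a2]: coords[:, 1] if len(selected) else []})
        t = model.super_scores[:, [a1, a2]]
        t_radius = np.linalg.norm(t, axis=1).max()
        score_df = pd.DataFrame(
            t * (display_radius / t_radius if t_radius > 0 else 1.0),
            columns=[AXIS_NAMES[a1], AXIS_NAMES[a2]])
        out[name + "/scores"] = score_df
        out[name + "/variables"] = var_df
    return out


def discriminant_table(selected: list[DiscriminantVariable]) -> pd.DataFrame:
    """Tabular export: (component_axis, block, variable_id, weight,
    increased_in) — the statistical skeleton of a per-axis marker table."""
    return pd.DataFrame(
        [(v.axis_name, v.block_id, v.variable_id, v.weight,
          "/".join(v.increased_in), "" if v.stable is None
          else ("stable" if v.stable else "unstable"))
         for v in selected],
        columns=["component_axis", "block", "variable_id", "weight",
                 "increased_in", "stability"])


def _align_components(ref_scores: np.ndarray, fold_scores: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Match fold components to reference components by score correlation.

    Latent components may swap order or flip sign between resampled fits;
    comparing weights axis-by-axis without alignment would label even a
    perfectly reproducible model unstable.  Returns, for each reference
    axis, the index of the best-matching fold axis and the sign of the
    match (+1/-1); assignment maximises total |correlation|.
    """
    from scipy.optimize import linear_sum_assignment
    A = ref_scores.shape[1]
    corr = np.zeros((A, A))
    for a in range(A):
        for b in range(A):
            r = np.corrcoef(ref_scores[:, a], fold_scores[:, b])[0, 1]
            corr[a, b] = 0.0 if np.isnan(r) else r
    rows, cols = linear_sum_assignment(-np.abs(corr))
    signs = np.sign(corr[rows, cols])
    signs[signs == 0] = 1
    return cols, signs


def plot_biplot(model: MBPLSModel, design: StudyDesign,
                selected: list[DiscriminantVariable] | None = None,
                panel: tuple = (0, 1), path=None):
    """Basic score/loading biplot figure for one component panel.

    Samples are drawn per condition group; selected variables as arrows
    coloured by block.  Requires matplotlib (optional dependency); returns
    the figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    coords = biplot_coordinates(model, selected or [], panels=(panel,))
    name = f"{AXIS_NAMES[panel[0]]}-{AXIS_NAMES[panel[1]]}"
    scores = coords[name + "/scores"]
    var_df = coords[name + "/variables"]
    fig, ax = plt.subplots(figsize=(6, 6))
    cond = np.asarray(design.conditions)
    for g in design.groups:
        sub = scores[cond == g]
        ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], label=g, s=40)
    for _, row in var_df.iterrows():
        x, y = row.iloc[2], row.iloc[3]
        ax.annotate("", xy=(x, y), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", alpha=0.4))
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(AXIS_NAMES[panel[0]])
    ax.set_ylabel(AXIS_NAMES[panel[1]])
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def selection_stability(blocks_raw: list[BlockMatrix], design: StudyDesign,
                        selected: list[DiscriminantVariable],
                        params: PreprocessParams | None = None,
                        n_components: int = 4, rule: str = "range-quarter",
                        fraction: float = 0.75,
                        model: MBPLSModel | None = None,
                        align: bool = False
                        ) -> list[DiscriminantVariable]:
    """Flag each selected variable stable/unstable across LOO folds.

    The model is refit on every leave-one-out training fold (full
    preprocessing refit included).  A variable is *stable* when its weight
    keeps one sign across all folds and it passes the selection rule in at
    least half of them.

    With ``align=False`` (default) fold axes are compared as fitted, in the
    canonical sign frame: when the data carry no real group structure the
    near-degenerate components rotate freely under resampling, so chance
    selections show sign flips and are flagged unstable.  ``align=True``
    first matches fold components to the reference model by super-score
    correlation, the appropriate frame when several genuine components of
    comparable strength may swap order between folds.
    """
    params = params or PreprocessParams()
    n = len(design.samples)
    if model is None:
        _, fitted = StudyPreprocessor.fit(blocks_raw, params)
        model = fit_mbpls(fitted, design.response_matrix(), n_components)
    votes = {(v.block_id, v.variable_index, v.axis): [] for v in selected}
    signs = {k: [] for k in votes}
    for i in range(n):
        train = np.delete(np.arange(n), i)
        pre, tblocks = StudyPreprocessor.fit(
            [b.subset_samples(train) for b in blocks_raw], params)
        Ytr = design.subset(train).response_matrix()
        fold = fit_mbpls(tblocks, Ytr, n_components)
        if align:
            axis_map, axis_sign = _align_components(
                model.super_scores[train], fold.super_scores)
        else:
            axis_map = np.arange(fold.n_components)
            axis_sign = np.ones(fold.n_components)
        for (bid, j, axis) in votes:
            w = fold.block_weights[bid][:, axis_map[axis]]
            thr = selection_threshold(np.abs(w), rule, fraction)
            votes[(bid, j, axis)].append(abs(w[j]) >= thr)
            signs[(bid, j, axis)].append(axis_sign[axis] * np.sign(w[j]))
    for v in selected:
        key = (v.block_id, v.variable_index, v.axis)
        sign_stable = len({s for s in signs[key] if s != 0}) <= 1
        v.stable = bool(sign_stable and np.mean(votes[key]) >= 0.5)
    return selected
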