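"""Bilateral symmetry decomposition, Procrustes ANOVA, and FA indices.

Two bilateral designs are supported:

* **matching symmetry** -- the structure exists as two separate copies
  (left and right wings).  Left-side configurations are mirrored about
  a fixed axis and the whole sample is superimposed jointly.
* **object symmetry** -- one structure with an internal midline (a
  head).  Each configuration is doubled with a mirrored copy whose
  paired landmarks are relabelled (midline landmarks keep their
  labels), and the doubled sample is superimposed jointly.  The
  symmetric component of a specimen is the mean of original and
  mirrored copy; the asymmetric component is half their difference.

Variance is partitioned Goodall-style: sums of squares are summed over
all landmarks and both coordinates at each stratum of the nested
design (location -> individual -> side -> side-by-individual
interaction = fluctuating asymmetry -> imaging error -> digitizing
error), degrees of freedom are the conventional univariate df times the
shape-space dimension, and each F ratio uses the next stratum down as
its denominator.  The shape dimension is 2k - 4 for matching symmetry;
for object symmetry with p landmark pairs and m midline landmarks the
symmetric and asymmetric subspaces each have dimension 2p + m - 2
(which sum to 2k - 4; this is asserted).

The size-based FA2 index of Palmer & Strobeck, (R - L)/((R + L)/2)
with R and L the right- and left-side centroid sizes, is provided
alongside a shape-asymmetry score (the Procrustes distance between an
individual's sides after removing the sample-mean directional
asymmetry).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .landmark_io import LandmarkDataset, validate_pairing, warn_excluded
from .procrustes import centroid_size, gpa, reflect

__all__ = [
    "SymmetryDecomposition",
    "matching_decomposition",
    "object_decomposition",
    "decompose",
    "procrustes_anova",
    "error_study",
    "fa2",
    "fa_scores",
]

ANOVA_COLUMNS = ["effect", "SS", "MS", "df", "F", "p"]


@dataclass
class SymmetryDecomposition:
    """Superimposed dataset ready for Procrustes ANOVA and FA scoring."""

    mode: str  # "matching" or "object"
    coords: np.ndarray  # (n, k, 2) aligned; in object mode includes mirrored copies
    meta: pd.DataFrame  # individual, side, image_rep, digit_rep, location, nest, species, sizes
    consensus: np.ndarray
    k: int
    pairing: list = field(default_factory=list)
    midline: list = field(default_factory=list)

    @property
    def shape_dim(self) -> int:
        return 2 * self.k - 4

    @property
    def component_dims(self) -> tuple[int, int]:
        """(symmetric, asymmetric) subspace dimensions."""
        if self.mode == "matching":
            d = self.shape_dim
            return d, d
        p, m = len(self.pairing), len(self.midline)
        sym = 2 * p + m - 2
        asym = 2 * p + m - 2
        assert sym + asym == self.shape_dim, "component dimensions must sum to 2k - 4"
        return sym, asym


def _meta_frame(dataset: LandmarkDataset, keep) -> pd.DataFrame:
    meta = dataset.classifier_frame()
    meta = meta.loc[keep].reset_index(drop=True)
    for col in ("image_rep", "digit_rep"):
        meta[col] = meta[col].astype(int)
    return meta


def matching_decomposition(dataset: LandmarkDataset, mirror_axis: str = "y") -> SymmetryDecomposition:
    """Superimpose a matching-symmetry dataset (e.g. left/right wings).

    All left-side configurations are reflected about ``mirror_axis`` so
    both sides live in one frame, then the whole sample is aligned by
    GPA.  Individuals missing a side are excluded with a warning.
    """
    if dataset.symmetry_mode != "matching":
        raise ValueError("dataset is not in matching symmetry mode")
    frame = dataset.classifier_frame()
    sides_per_ind = frame.groupby("individual")["side"].agg(lambda s: set(s))
    complete = sides_per_ind[sides_per_ind.apply(lambda s: {"left", "right"} <= s)].index
    excluded = set(sides_per_ind.index) - set(complete)
    warn_excluded(excluded, "missing a side")
    keep = frame.index[frame["individual"].isin(complete)].to_numpy()
    if len(keep) == 0:
        raise ValueError("no individual has both sides")

    meta = _meta_frame(dataset, keep)
    raw = [dataset.configs[i].coords for i in keep]
    meta["size"] = [centroid_size(c) for c in raw]
    arr = np.stack(
        [reflect(c, mirror_axis) if s == "left" else c for c, s in zip(raw, meta["side"])]
    )
    res = gpa(arr)
    return SymmetryDecomposition(
        mode="matching", coords=res.aligned, meta=meta, consensus=res.consensus, k=dataset.k
    )


def _mirror_relabel(coords: np.ndarray, perm: np.ndarray, mirror_axis: str) -> np.ndarray:
    return reflect(coords, mirror_axis)[perm]


def object_decomposition(dataset: LandmarkDataset, mirror_axis: str = "y") -> SymmetryDecomposition:
    """Superimpose an object-symmetry dataset with reflected-relabelled copies.

    Each configuration is paired with its mirror image in which the
    paired landmark labels are swapped; the doubled sample is aligned
    jointly.  The per-configuration left/right centroid sizes of the
    pairing-defined landmark subsets are recorded for FA2 scoring.
    """
    if dataset.symmetry_mode != "object":
        raise ValueError("dataset is not in object symmetry mode")
    pairing = validate_pairing(dataset.pairing, dataset.midline, dataset.k)
    perm = np.arange(dataset.k)
    for left, right in pairing:
        perm[left - 1], perm[right - 1] = right - 1, left - 1

    frame = dataset.classifier_frame()
    meta = _meta_frame(dataset, frame.index.to_numpy())
    left_idx = np.array([p[0] - 1 for p in pairing])
    right_idx = np.array([p[1] - 1 for p in pairing])
    raw = [c.coords for c in dataset.configs]
    meta["size"] = [centroid_size(c) for c in raw]
    meta["size_left"] = [centroid_size(c[left_idx]) for c in raw]
    meta["size_right"] = [centroid_size(c[right_idx]) for c in raw]

    originals = np.stack(raw)
    mirrored = np.stack([_mirror_relabel(c, perm, mirror_axis) for c in raw])
    doubled = np.concatenate([originals, mirrored])
    meta_orig = meta.copy()
    meta_orig["reflection"] = "orig"
    meta_mirr = meta.copy()
    meta_mirr["reflection"] = "mirror"
    meta2 = pd.concat([meta_orig, meta_mirr], ignore_index=True)
    # side of the doubled copies is the reflection label, used as the
    # ANOVA side factor
    meta2["side"] = meta2["reflection"]

    res = gpa(doubled)
    return SymmetryDecomposition(
        mode="object",
        coords=res.aligned,
        meta=meta2,
        consensus=res.consensus,
        k=dataset.k,
        pairing=pairing,
        midline=list(dataset.midline),
    )


def decompose(dataset: LandmarkDataset, mirror_axis: str = "y") -> SymmetryDecomposition:
    """Dispatch to matching or object decomposition by dataset mode."""
    if dataset.symmetry_mode == "matching":
        return matching_decomposition(dataset, mirror_axis)
    return object_decomposition(dataset, mirror_axis)


# ---------------------------------------------------------------------------
# Procrustes ANOVA
# ---------------------------------------------------------------------------

def _partition_fit(Y: np.ndarray, codes: np.ndarray):
    """Fitted SS and group count for a partition given integer group codes."""
    n_groups = codes.max() + 1
    sums = np.zeros((n_groups, Y.shape[1]))
    np.add.at(sums, codes, Y)
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    means = sums / counts[:, None]
    return float((counts[:, None] * means**2).sum()), int(n_groups)


def _codes(meta: pd.DataFrame, cols) -> np.ndarray:
    key = meta[list(cols)].astype(str).agg("|".join, axis=1)
    return pd.factorize(key)[0]


def default_effects(decomp: SymmetryDecomposition) -> list[str]:
    """Effect list inferred from the classifier structure."""
    meta = decomp.meta
    effects = []
    if meta["location"].notna().any() and meta["location"].nunique() > 1:
        effects.append("location")
    if meta["nest"].notna().any() and meta["nest"].nunique() > 1:
        effects.append("nest")
    effects += ["individual", "directional_asymmetry", "fluctuating_asymmetry"]
    if meta["image_rep"].max() > 1:
        effects.append("imaging_error")
    if meta["digit_rep"].max() > 1:
        effects.append("digitizing_error")
    return effects


_EFFECT_PARTITIONS = {
    "location": ("location",),
    "nest": ("location", "nest"),
    "individual": ("individual",),
    "fluctuating_asymmetry": ("individual", "side"),
    "imaging_error": ("individual", "side", "image_rep"),
    "digitizing_error": ("individual", "side", "image_rep", "digit_rep"),
}


def procrustes_anova(
    decomp: SymmetryDecomposition, effects: list[str] | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Goodall-style Procrustes ANOVA over the superimposed coordinates.

    ``effects`` is the ordered stratum list; the last listed effect is
    the residual stratum and carries no F or p.  Sums of squares are
    sequential (Type I) over the nested design, computed by orthogonal
    projection, so they are additive by construction: the effect SS sum
    to the total SS exactly.  F for each effect is its MS over the MS
    of the next stratum down.

    Returns a DataFrame with columns effect, SS, MS, df, F, p and table
    metadata in ``.attrs`` (total SS, balance flag, residual effect).
    """
    if effects is None:
        effects = default_effects(decomp)
    if "individual" not in effects or "fluctuating_asymmetry" not in effects:
        raise ValueError("effects must include 'individual' and 'fluctuating_asymmetry'")
    meta = decomp.meta
    n = len(meta)
    Y = decomp.coords.reshape(n, -1)
    grand = Y.mean(axis=0)
    Yc = Y - grand
    total_ss = float((Yc**2).sum())

    cell_counts = meta.groupby(["individual", "side"], dropna=False).size()
    balanced = cell_counts.nunique() == 1
    if not balanced:
        warnings.warn("unbalanced replicate structure; sequential SS computed by projection")

    dim_sym, dim_asym = decomp.component_dims
    full_dim = decomp.shape_dim
    dims = {
        "location": dim_sym,
        "nest": dim_sym,
        "individual": dim_sym,
        "directional_asymmetry": dim_asym,
        "fluctuating_asymmetry": dim_asym,
        "imaging_error": full_dim,
        "digitizing_error": full_dim,
    }

    fitted = 0.0
    groups_so_far = 1
    rows = []
    for pos, effect in enumerate(effects):
        is_last = pos == len(effects) - 1
        if is_last:
            ss = total_ss - fitted
            udf = n - groups_so_far
        elif effect == "directional_asymmetry":
            # span(individual) + side main effect: one extra rank
            ind_codes = _codes(meta, ("individual",))
            side = (pd.factorize(meta["side"])[0]).astype(float)
            n_ind = ind_codes.max() + 1
            X = np.zeros((n, n_ind + 1))
            X[np.arange(n), ind_codes] = 1.0
            X[:, -1] = side
            beta, *_ = np.linalg.lstsq(X, Yc, rcond=None)
            fit_ss = float((X @ beta * Yc).sum())
            ss = fit_ss - fitted
            fitted = fit_ss
            udf = 1
            groups_so_far += 1
        else:
            codes = _codes(meta, _EFFECT_PARTITIONS[effect])
            fit_ss, n_groups = _partition_fit(Yc, codes)
            ss = fit_ss - fitted
            fitted = fit_ss
            udf = n_groups - groups_so_far
            groups_so_far = n_groups
        ss = max(ss, 0.0)
        df = udf * dims[effect]
        if df <= 0:
            raise ValueError(f"effect {effect!r} has no degrees of freedom (udf={udf})")
        rows.append({"effect": effect, "SS": ss, "MS": ss / df, "df": df})

    for i, row in enumerate(rows):
        if i + 1 < len(rows) and rows[i + 1]["MS"] > 0:
            row["F"] = row["MS"] / rows[i + 1]["MS"]
            row["p"] = float(stats.f.sf(row["F"], row["df"], rows[i + 1]["df"]))
        else:
            row["F"] = np.nan
            row["p"] = np.nan

    table = pd.DataFrame(rows, columns=ANOVA_COLUMNS)
    if decomp.mode == "object":
        # the doubled set counts every measurement twice
        table["SS"] /= 2.0
        table["MS"] /= 2.0
        total_ss /= 2.0
    table.attrs["total_SS"] = total_ss
    table.attrs["balanced"] = bool(balanced)
    table.attrs["residual_effect"] = effects[-1]
    table.attrs["alpha"] = alpha
    return table


def error_study(decomp: SymmetryDecomposition, alpha: float = 0.05):
    """Measurement-error validation on the replicated subset.

    Restricts the decomposition to individuals digitized (and, when
    available, imaged) more than once, runs the Procrustes ANOVA, and
    reports per-stratum verdicts: an error stratum is *nonsignificant*
    when its F against the next stratum down does not reach ``alpha``,
    and the study passes when, in addition, the individual and
    fluctuating-asymmetry mean squares exceed the first error-stratum
    mean square.

    Returns ``(anova_table, verdict_dict)``.  Raises if no replication
    exists.
    """
    meta = decomp.meta
    rep_counts = meta.groupby("individual")[["image_rep", "digit_rep"]].max()
    replicated = rep_counts[(rep_counts["image_rep"] > 1) | (rep_counts["digit_rep"] > 1)].index
    if len(replicated) == 0:
        raise ValueError(
            "error study requires repeated imaging or digitizing; no individual has "
            "image_rep or digit_rep above 1"
        )
    keep = meta["individual"].isin(replicated).to_numpy()
    sub = SymmetryDecomposition(
        mode=decomp.mode,
        coords=decomp.coords[keep],
        meta=meta.loc[keep].reset_index(drop=True),
        consensus=decomp.consensus,
        k=decomp.k,
        pairing=decomp.pairing,
        midline=decomp.midline,
    )
    table = procrustes_anova(sub, alpha=alpha)
    by_effect = table.set_index("effect")
    error_strata = [e for e in ("imaging_error", "digitizing_error") if e in by_effect.index]
    verdict = {}
    testable = []
    for e in error_strata:
        p = by_effect.loc[e, "p"]
        if np.isfinite(p):
            verdict[e] = "nonsignificant" if p >= alpha else "significant"
            testable.append(p >= alpha)
        else:
            verdict[e] = "residual stratum (no denominator)"
    first_error_ms = by_effect.loc[error_strata[0], "MS"]
    verdict["ms_individual_exceeds_error"] = bool(by_effect.loc["individual", "MS"] > first_error_ms)
    verdict["ms_fa_exceeds_error"] = bool(
        by_effect.loc["fluctuating_asymmetry", "MS"] > first_error_ms
    )
    verdict["errors_nonsignificant"] = bool(all(testable)) if testable else True
    fa_p = by_effect.loc["fluctuating_asymmetry", "p"]
    verdict["fa_significant"] = bool(np.isfinite(fa_p) and fa_p < alpha)
    return table, verdict


# ---------------------------------------------------------------------------
# FA indices
# ---------------------------------------------------------------------------

def fa2(R: float, L: float) -> float:
    """Size FA index 2: (R - L) / ((R + L) / 2).

    Signed (right minus left), antisymmetric under swapping the sides,
    and invariant to a common rescaling of both sizes.
    """
    if R <= 0 or L <= 0:
        raise ValueError(f"side sizes must be positive, got R={R}, L={L}")
    return (R - L) / ((R + L) / 2.0)


def fa_scores(decomp: SymmetryDecomposition) -> pd.DataFrame:
    """Per-individual FA scores from a completed decomposition.

    Replicate measurements are averaged before scoring.  ``fa2_size``
    uses the per-side centroid sizes of the raw configurations (for
    object symmetry, of the pairing-defined left and right landmark
    subsets).  ``fa_shape`` is the Procrustes distance between an
    individual's side configurations after subtracting the sample-mean
    directional asymmetry.

    Returns a DataFrame indexed by individual with columns fa2_size,
    fa_shape, size_right, size_left plus any group labels present.
    """
    meta = decomp.meta
    n = len(meta)
    flat = decomp.coords.reshape(n, -1)

    if decomp.mode == "matching":
        frame = meta[["individual", "side", "size"]].copy()
        size_by = frame.groupby(["individual", "side"])["size"].mean().unstack("side")
        shape_by = (
            pd.DataFrame(flat)
            .groupby([meta["individual"], meta["side"]])
            .mean()
        )
        right = shape_by.xs("right", level="side")
        left = shape_by.xs("left", level="side")
        diffs = right - left.loc[right.index]
        da = diffs.mean(axis=0)
        corrected = diffs - da
        fa_shape = np.sqrt((corrected**2).sum(axis=1))
        sizes_r = size_by["right"]
        sizes_l = size_by["left"]
    else:
        orig = meta["reflection"] == "orig"
        mirr = meta["reflection"] == "mirror"
        shapes_o = pd.DataFrame(flat[orig.to_numpy()]).groupby(
            meta.loc[orig, "individual"].to_numpy()
        ).mean()
        shapes_m = pd.DataFrame(flat[mirr.to_numpy()]).groupby(
            meta.loc[mirr, "individual"].to_numpy()
        ).mean()
        asym = (shapes_o - shapes_m.loc[shapes_o.index]) / 2.0
        da = asym.mean(axis=0)
        corrected = asym - da
        # distance between the two side configurations = 2 * |asymmetric part|
        fa_shape = 2.0 * np.sqrt((corrected**2).sum(axis=1))
        size_frame = meta.loc[orig, ["individual", "size_left", "size_right"]]
        by_ind = size_frame.groupby("individual").mean()
        sizes_r = by_ind["size_right"]
        sizes_l = by_ind["size_left"]

    out = pd.DataFrame(
        {
            "size_right": sizes_r,
            "size_left": sizes_l,
            "fa_shape": fa_shape,
        }
    ).dropna(subset=["size_right", "size_left"])
    out["fa2_size"] = [fa2(r, l) for r, l in zip(out["size_right"], out["size_left"])]
    for label in ("location", "nest", "species"):
        if label in meta.columns and meta[label].notna().any():
            out[label] = meta.groupby("individual")[label].first().reindex(out.index)
    out.index.name = "individual"
    return out[["fa2_size", "fa_shape", "size_right", "size_left"]
               + [c for c in ("location", "nest", "species") if c in out.columns]]
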