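"""Fluctuating-asymmetry statistics for matching symmetry.

The measurement design is a two-factor mixed model — individual (random) x
side (fixed) — with two nested measurement-error strata below the
individual-x-side cell: image replicates (repeat photographs of the same
side) and digitizing replicates (repeat landmark inputs on the same
photograph).  Fluctuating asymmetry (FA) is the individual-x-side
interaction; directional asymmetry (DA) is the side main effect.

Shape variation is analyzed by Procrustes ANOVA: sums of squared deviations
of aligned Procrustes coordinates, summed over all 2k coordinates, with
structural degrees of freedom multiplied by the shape-space dimension 2k - 4
(2-D data after removing translation, scale and rotation).  Size uses the
same strata on scalar centroid size without the multiplier.

Sums of squares are sequential (Type I) on the nested hierarchy

    individual -> side -> individual x side -> image -> digitizing,

computed by comparing least-squares fits of successive design matrices; for
balanced data this reduces exactly to the classical group-mean decomposition,
and for unbalanced data the degrees of freedom come from observed design
ranks rather than nominal counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gpa import ProcrustesResult
from .tpsio import ReplicateDesign

__all__ = [
    "procrustes_anova",
    "size_anova",
    "detect_fa",
    "mahalanobis_shape_fa",
    "size_fa_index",
    "fa_scores",
    "variance_components",
    "AnovaResults",
    "FADetection",
    "FluctuatingAsymmetryModel",
    "FAResults",
]

EFFECTS = ["individual", "side", "individual_x_side", "error1", "residual"]
# F-test denominators: main effects against the FA interaction, the
# interaction against the image stratum, the image stratum against digitizing.
_DENOMS = {
    "individual": "individual_x_side",
    "side": "individual_x_side",
    "individual_x_side": "error1",
    "error1": "residual",
}


def _group_rss(Y: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Residual SS around group means (partition model)."""
    p = Y.shape[1]
    sums = np.zeros((n_groups, p))
    np.add.at(sums, codes, Y)
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    means = sums / counts[:, None]
    return float(((Y - means[codes]) ** 2).sum())


def _codes(values) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(values), sort=True)
    return codes.astype(np.intp), len(uniques)


def _combine(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, int]:
    """Codes of the crossed factor a x b, renumbered to observed cells."""
    return _codes(a.astype(np.int64) * (b.max() + 1) + b)


def _hierarchical_anova(Y: np.ndarray, keys: pd.DataFrame) -> tuple[dict, dict]:
    """Sequential SS and structural df for the nested symmetry design."""
    n = Y.shape[0]
    spec, n_spec = _codes(keys["specimen_id"])
    side, n_side = _codes(keys["side"])
    if n_side < 2:
        raise ValueError("both sides are required for a symmetry ANOVA")
    if n_spec < 2:
        raise ValueError("at least two individuals are required")
    cell, n_cell = _combine(spec, side)
    img_code, _ = _codes(keys["image_rep"])
    img, n_img = _combine(cell, img_code)

    grand = Y.mean(axis=0)
    tss = float(((Y - grand) ** 2).sum())

    rss_ind = _group_rss(Y, spec, n_spec)

    # individual + side: not a partition -> least-squares fit
    X = np.zeros((n, n_spec + n_side - 1))
    X[np.arange(n), spec] = 1.0
    for s in range(1, n_side):
        X[:, n_spec + s - 1] = (side == s)
    beta, _, rank2, _ = np.linalg.lstsq(X, Y, rcond=None)
    rss_side = float(((Y - X @ beta) ** 2).sum())
    df_side = int(rank2) - n_spec

    rss_cell = _group_rss(Y, cell, n_cell)
    rss_img = _group_rss(Y, img, n_img)

    ss = {
        "individual": tss - rss_ind,
        "side": rss_ind - rss_side,
        "individual_x_side": rss_side - rss_cell,
        "error1": rss_cell - rss_img,
        "residual": rss_img,
    }
    df = {
        "individual": n_spec - 1,
        "side": df_side,
        "individual_x_side": n_cell - int(rank2),
        "error1": n_img - n_cell,
        "residual": n - n_img,
    }
    # numerical floor: sequential SS are non-negative up to round-off
    ss = {k: max(v, 0.0) for k, v in ss.items()}
    return ss, df


@dataclass
class FADetection:
    """Outcome of the FA detection rule: the individual-x-side interaction
    must be significant *and* its F must exceed ``f_ratio`` times the F of
    the measurement-error stratum."""

    detected: bool
    p_significant: bool
    f_ratio_exceeded: bool
    interaction_f: float
    interaction_p: float
    error_f: float
    p_threshold: float
    f_ratio: float


class AnovaResults:
    """ANOVA table for one trait (shape or size) with stratified F tests."""

    def __init__(self, table: pd.DataFrame, trait: str, design: ReplicateDesign,
                 shape_dim: int | None = None):
        self.table = table
        self.trait = trait
        self.design = design
        self.shape_dim = shape_dim  # 2k - 4 multiplier used (None for size)

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.loc[effect]

    def detect_fa(self, p_threshold: float = 0.05, f_ratio: float = 10.0) -> FADetection:
        return detect_fa(self, p_threshold=p_threshold, f_ratio=f_ratio)

    def variance_components(self) -> dict:
        return variance_components(self)

    def summary(self) -> str:
        lines = [f"ANOVA for {self.trait} (denominators: stratified F tests)"]
        with pd.option_context("display.float_format", lambda v: f"{v:.6g}"):
            lines.append(self.table.to_string())
        det = self.detect_fa()
        lines.append(
            f"FA detection: {'DETECTED' if det.detected else 'not detected'} "
            f"(interaction F={det.interaction_f:.3f}, p={det.interaction_p:.4g}, "
            f"error F={det.error_f:.3f})"
        )
        return "\n".join(lines)


def _build_table(ss: dict, df_struct: dict, mult: int) -> pd.DataFrame:
    rows = []
    df = {k: v * mult for k, v in df_struct.items()}
    ms = {k: (ss[k] / df[k] if df[k] > 0 else np.nan) for k in EFFECTS}
    for eff in EFFECTS:
        den = _DENOMS.get(eff)
        if den is not None and df[eff] > 0 and df[den] > 0 and ms[den] > 0:
            F = ms[eff] / ms[den]
            p = float(stats.f.sf(F, df[eff], df[den]))
        else:
            F, p = np.nan, np.nan
        rows.append((eff, ss[eff], df[eff], ms[eff], F, p, den or ""))
    out = pd.DataFrame(rows, columns=["effect", "SS", "df", "MS", "F", "p", "denominator"])
    return out.set_index("effect")


def procrustes_anova(result: ProcrustesResult, design: ReplicateDesign | None = None) -> AnovaResults:
    """Procrustes ANOVA for shape on aligned coordinates.

    SS are summed across all 2k coordinates; structural df are multiplied by
    the shape-space dimension 2k - 4.  Goodall-style F ratios and p-values
    from the F distribution.
    """
    n, k, _ = result.aligned.shape
    Y = result.aligned.reshape(n, 2 * k)
    ss, df_struct = _hierarchical_anova(Y, result.keys)
    mult = 2 * k - 4
    if mult <= 0:
        raise ValueError("need at least 3 landmarks for a shape ANOVA")
    table = _build_table(ss, df_struct, mult)
    return AnovaResults(table, trait="shape", design=design or _design_of(result), shape_dim=mult)


def size_anova(result: ProcrustesResult, design: ReplicateDesign | None = None) -> AnovaResults:
    """Factorial ANOVA on scalar centroid size with the same strata as the
    shape analysis (no shape-dimension multiplier)."""
    Y = result.centroid_sizes.reshape(-1, 1).astype(float)
    ss, df_struct = _hierarchical_anova(Y, result.keys)
    table = _build_table(ss, df_struct, 1)
    return AnovaResults(table, trait="size", design=design or _design_of(result), shape_dim=None)


def _design_of(result: ProcrustesResult) -> ReplicateDesign:
    return ReplicateDesign(
        n_images=int(result.keys["image_rep"].max()),
        n_digitizings=int(result.keys["digit_rep"].max()),
    )


def detect_fa(anova: AnovaResults, p_threshold: float = 0.05, f_ratio: float = 10.0) -> FADetection:
    """FA is declared present when the individual-x-side interaction has
    p below ``p_threshold`` and its F exceeds ``f_ratio`` times the F of the
    measurement-error stratum."""
    table = anova.table
    for eff in ("individual_x_side", "error1"):
        if eff not in table.index:
            raise ValueError(f"ANOVA table lacks the {eff} row")
    f_int = float(table.loc["individual_x_side", "F"])
    p_int = float(table.loc["individual_x_side", "p"])
    f_err = float(table.loc["error1", "F"])
    p_ok = bool(p_int < p_threshold)
    ratio_ok = bool(f_int > f_ratio * f_err)
    return FADetection(
        detected=p_ok and ratio_ok,
        p_significant=p_ok,
        f_ratio_exceeded=ratio_ok,
        interaction_f=f_int,
        interaction_p=p_int,
        error_f=f_err,
        p_threshold=p_threshold,
        f_ratio=f_ratio,
    )


def variance_components(anova: AnovaResults) -> dict:
    """Method-of-moments variance components from expected mean squares.

    With m images per side and d digitizings per image (nominal design
    counts), per coordinate:

        E[MS_residual] = s2_digit
        E[MS_error1]   = s2_digit + d * s2_image
        E[MS_int]      = s2_digit + d * s2_image + m*d/2 * s2_fa

    where s2_fa is the variance of the *signed left-minus-right* asymmetry
    per coordinate (the factor 2 arises because each side carries half the
    asymmetry deviation).
    """
    t = anova.table
    m = anova.design.n_images
    d = anova.design.n_digitizings
    ms_res = float(t.loc["residual", "MS"])
    ms_e1 = float(t.loc["error1", "MS"])
    ms_int = float(t.loc["individual_x_side", "MS"])
    s2_digit = ms_res
    s2_image = (ms_e1 - ms_res) / d
    s2_fa = 2.0 * (ms_int - ms_e1) / (m * d)
    return {"sigma2_fa": s2_fa, "sigma2_image": s2_image, "sigma2_digit": s2_digit}


# ---------------------------------------------------------------------------
# Individual FA indices


def _side_means(result: ProcrustesResult) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Replicate-averaged aligned coordinates and centroid sizes per
    specimen x side.  Returns (meta, mean_coords (g, 2k), mean_sizes (g,))."""
    n, k, _ = result.aligned.shape
    flat = result.aligned.reshape(n, 2 * k)
    df = result.keys.copy()
    df["_row"] = np.arange(n)
    groups = df.groupby(["specimen_id", "side"], sort=True)
    metas, coords, sizes = [], [], []
    for (spec, side), g in groups:
        rows = g["_row"].to_numpy()
        metas.append((spec, g["population"].iloc[0], side, len(rows)))
        coords.append(flat[rows].mean(axis=0))
        sizes.append(result.centroid_sizes[rows].mean())
    meta = pd.DataFrame(metas, columns=["specimen_id", "population", "side", "n_reps"])
    return meta, np.asarray(coords), np.asarray(sizes)


def mahalanobis_shape_fa(result: ProcrustesResult, rank_tol: float = 1e-10) -> pd.DataFrame:
    """Mahalanobis FA score for shape, per specimen.

    The asymmetry vector of specimen i is the difference between its
    replicate-averaged left and (reflected) right aligned configurations.
    Directional asymmetry — the mean asymmetry across specimens — is removed,
    and each centered asymmetry d_i is standardized by the covariance S of
    those deviations:  score_i = sqrt(d_i' S+ d_i), with S+ the pseudo-inverse
    restricted to eigenvalues above ``rank_tol`` times the largest (shape
    space is rank-deficient).
    """
    meta, coords, _ = _side_means(result)
    piv: dict[str, dict[str, np.ndarray]] = {}
    pops: dict[str, str] = {}
    for i, row in meta.iterrows():
        piv.setdefault(row.specimen_id, {})[row.side] = coords[i]
        pops[row.specimen_id] = row.population
    specs = [s for s in sorted(piv) if set(piv[s]) == {"left", "right"}]
    if len(specs) < 2:
        raise ValueError("need at least two specimens with both sides")
    A = np.stack([piv[s]["left"] - piv[s]["right"] for s in specs])
    D = A - A.mean(axis=0)
    S = np.cov(D, rowvar=False)
    evals, evecs = np.linalg.eigh(S)
    keep = evals > rank_tol * evals.max()
    inv = (evecs[:, keep] / evals[keep]) @ evecs[:, keep].T
    scores = np.sqrt(np.einsum("ij,jk,ik->i", D, inv, D))
    return pd.DataFrame(
        {
            "specimen_id": specs,
            "population": [pops[s] for s in specs],
            "shape_fa": scores,
        }
    )


def size_fa_index(result: ProcrustesResult) -> pd.DataFrame:
    """Signed and absolute centroid-size FA index per specimen.

    signed = mean over replicates of CS(left) minus CS(right); positive when
    the left side is larger.  The absolute value discards direction.
    Specimens missing a side are skipped (listed in the ``skipped`` attribute
    of the returned frame).
    """
    meta, _, sizes = _side_means(result)
    piv: dict[str, dict[str, float]] = {}
    pops: dict[str, str] = {}
    for i, row in meta.iterrows():
        piv.setdefault(row.specimen_id, {})[row.side] = sizes[i]
        pops[row.specimen_id] = row.population
    rows, skipped = [], []
    for s in sorted(piv):
        if set(piv[s]) != {"left", "right"}:
            skipped.append(s)
            continue
        signed = piv[s]["left"] - piv[s]["right"]
        rows.append((s, pops[s], signed, abs(signed)))
    out = pd.DataFrame(rows, columns=["specimen_id", "population", "size_fa_signed", "size_fa_abs"])
    out.attrs["skipped"] = skipped
    return out


def fa_scores(result: ProcrustesResult) -> pd.DataFrame:
    """Combined per-specimen FA score table (shape + size indices)."""
    shape = mahalanobis_shape_fa(result)
    size = size_fa_index(result)
    return shape.merge(size, on=["specimen_id", "population"], how="inner")


# ---------------------------------------------------------------------------
# Model/Results front-end


@dataclass
class FAResults:
    """Fitted FA analysis: ANOVA tables, detection decisions, and indices."""

    shape_anova: AnovaResults
    size_anova: AnovaResults
    shape_detection: FADetection
    size_detection: FADetection
    scores: pd.DataFrame
    procrustes: ProcrustesResult = field(repr=False)

    def summary(self) -> str:
        parts = [self.shape_anova.summary(), "", self.size_anova.summary(), ""]
        pop = self.scores.groupby("population")[["shape_fa", "size_fa_abs"]].agg(["mean", "var"])
        parts.append("Per-population FA indices:")
        parts.append(pop.to_string())
        return "\n".join(parts)


class FluctuatingAsymmetryModel:
    """Matching-symmetry FA analysis of an aligned landmark dataset.

    Parameters
    ----------
    procrustes : ProcrustesResult
        Output of :func:`fluctasym.gpa.gpa_align` on a side-reflected dataset.
    design : ReplicateDesign, optional
        Nominal replicate structure; inferred from the data when omitted.
    """

    def __init__(self, procrustes: ProcrustesResult, design: ReplicateDesign | None = None):
        self.procrustes = procrustes
        self.design = design or _design_of(procrustes)

    def fit(self, p_threshold: float = 0.05, f_ratio: float = 10.0) -> FAResults:
        shape = procrustes_anova(self.procrustes, self.design)
        size = size_anova(self.procrustes, self.design)
        return FAResults(
            shape_anova=shape,
            size_anova=size,
            shape_detection=shape.detect_fa(p_threshold, f_ratio),
            size_detection=size.detect_fa(p_threshold, f_ratio),
            scores=fa_scores(self.procrustes),
            procrustes=self.procrustes,
        )
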