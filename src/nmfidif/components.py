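"""Turn NMF factors into labeled anatomical regions and the NMF-IDIF.

A voxel's relative probability of belonging to component i is its NMF
weight normalized over components, r_ij = h_ij / sum_i h_ij.  Voxels with
r > 0.9 (strict) define each component's region, and the region TAC is the
plain average of those voxels' measured TACs — the factor matrix G fixes
which component is which, but the activity scale and shape are read from
the data, not from G.

Labels come from kinetic ordering: the liver is the slow-uptake component;
among the rest the right ventricle peaks first, then the left ventricle,
then the myocardium.  The component count is chosen by increasing n until
two components become redundant (correlated TACs and probability maps, or
an identical peak frame) or the data cannot support another component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import Tac
from .unmix import (
    NmfDecomposition,
    RankDeficiencyError,
    VoxelTacMatrix,
    unmix_voi,
)

__all__ = [
    "ProbabilityMaps",
    "ComponentSet",
    "relative_probability",
    "select_region_voxels",
    "region_tac",
    "classify_components",
    "identify_components",
    "choose_n_components",
    "extract_nmf_idif",
]


@dataclass
class ProbabilityMaps:
    """Relative component probabilities per voxel.

    ``R`` is (n_components, n_voxels) with columns summing to 1 except for
    ``degenerate`` voxels (all-zero weights), which are excluded from any
    selection.
    """

    R: np.ndarray
    degenerate: np.ndarray  # boolean, per voxel

    def as_volume(self, component: int, voxel_indices: np.ndarray, grid_shape) -> np.ndarray:
        """Reassemble one component's probabilities on the image grid."""
        vol = np.zeros(grid_shape, dtype=float)
        idx = tuple(voxel_indices.T)
        vol[idx] = self.R[component]
        return vol


def relative_probability(H: np.ndarray) -> ProbabilityMaps:
    """Normalize NMF weights to per-voxel component probabilities."""
    H = np.asarray(H, dtype=float)
    if np.any(H < 0):
        raise ValueError("H must be non-negative")
    col_sums = H.sum(axis=0)
    degenerate = col_sums == 0
    R = np.zeros_like(H)
    ok = ~degenerate
    R[:, ok] = H[:, ok] / col_sums[ok]
    return ProbabilityMaps(R=R, degenerate=degenerate)


def select_region_voxels(
    maps: ProbabilityMaps, component: int, r_threshold: float = 0.9
) -> np.ndarray:
    """Column indices of voxels with r strictly above the threshold."""
    if not 0 < r_threshold < 1:
        raise ValueError("r_threshold must be in (0, 1)")
    return np.flatnonzero((maps.R[component] > r_threshold) & ~maps.degenerate)


def region_tac(Zmat: VoxelTacMatrix, voxels: np.ndarray) -> Tac:
    """Unweighted mean TAC of the selected matrix columns."""
    voxels = np.asarray(voxels, dtype=int)
    if voxels.size == 0:
        raise ValueError(
            "no voxels selected for this region; lower the probability "
            "threshold or use fewer components"
        )
    return Tac(
        Zmat.frame_mid_times_s,
        Zmat.frame_durations_s,
        Zmat.Z[:, voxels].mean(axis=1),
    )


def _peak_stats(values: np.ndarray, mid_times: np.ndarray):
    peak_frame = int(np.argmax(values))
    total = values.sum()
    com = float((mid_times * values).sum() / total) if total > 0 else np.inf
    return peak_frame, float(mid_times[peak_frame]), com


def _is_slow_uptake(values: np.ndarray, mid_times: np.ndarray, scan_end_s: float) -> bool:
    """Hepatic signature: peak in the final third of the scan, or late
    activity more than twice the early activity."""
    peak_time = mid_times[int(np.argmax(values))]
    if peak_time > (2.0 / 3.0) * scan_end_s:
        return True
    if len(values) >= 5:
        early = values[1:5].mean()
        late = values[-3:].mean()
        if early > 0 and late / early > 2.0:
            return True
    return False


def classify_components(G: np.ndarray, framing: np.ndarray) -> tuple[list, np.ndarray]:
    """Assign anatomical labels to the columns of G by kinetic ordering.

    Returns ``(labels, peak_times_s)``.  Liver components are identified
    first by their slow uptake; the remaining components are ordered by
    peak time and labeled (RV, LV, MYO) when three remain or (LV, MYO)
    when two remain.  Any other remainder count yields ``unknown`` labels
    with a warning.  Ties on the peak frame are broken by the earlier
    centre-of-mass time, with a warning.
    """
    G = np.asarray(G, dtype=float)
    framing = np.asarray(framing, dtype=float)
    mids = framing[:, 0] + framing[:, 1] / 2.0
    scan_end = float(framing[-1, 0] + framing[-1, 1])
    n = G.shape[1]
    labels: list[str] = ["unknown"] * n
    peak_times = np.empty(n)
    stats = []
    for i in range(n):
        pf, pt, com = _peak_stats(G[:, i], mids)
        peak_times[i] = pt
        stats.append((i, pf, pt, com))

    cardiac = []
    for i, pf, pt, com in stats:
        if _is_slow_uptake(G[:, i], mids, scan_end):
            labels[i] = "LIV"
        else:
            cardiac.append((i, pf, pt, com))

    peak_frames = [pf for _, pf, _, _ in cardiac]
    if len(set(peak_frames)) < len(peak_frames):
        warnings.warn(
            "components share a peak frame; breaking tie by centre-of-mass time",
            stacklevel=2,
        )
    cardiac.sort(key=lambda s: (s[1], s[3]))  # peak frame, then centre of mass
    order = {3: ["RV", "LV", "MYO"], 2: ["LV", "MYO"]}
    if len(cardiac) in order:
        for (i, *_), lab in zip(cardiac, order[len(cardiac)]):
            labels[i] = lab
    elif cardiac:
        warnings.warn(
            f"{len(cardiac)} non-liver components cannot be labeled by peak "
            "ordering; leaving them unknown",
            stacklevel=2,
        )
    return labels, peak_times


@dataclass
class ComponentSet:
    """Labeled decomposition: per-component maps, TACs and voxel selections."""

    n: int
    labels: list
    peak_times_s: np.ndarray
    component_tacs: np.ndarray  # G, (n_frames, n)
    maps: ProbabilityMaps
    selected_voxels: dict  # component index -> column indices
    region_tacs: dict  # label -> Tac (only for labeled, non-empty selections)

    def tac(self, label: str) -> Tac:
        try:
            return self.region_tacs[label]
        except KeyError:
            raise KeyError(
                f"no region TAC for {label!r}; available: {sorted(self.region_tacs)}"
            ) from None


def identify_components(
    Zmat: VoxelTacMatrix,
    decomp: NmfDecomposition,
    r_threshold: float = 0.9,
) -> ComponentSet:
    """Label an NMF decomposition and compute voxel-average region TACs."""
    maps = relative_probability(decomp.H)
    labels, peak_times = classify_components(decomp.G, Zmat.framing)
    selected = {
        i: select_region_voxels(maps, i, r_threshold) for i in range(decomp.n_components)
    }
    region_tacs = {}
    for i, label in enumerate(labels):
        if label == "unknown" or selected[i].size == 0:
            continue
        region_tacs[label] = region_tac(Zmat, selected[i])
    return ComponentSet(
        n=decomp.n_components,
        labels=labels,
        peak_times_s=peak_times,
        component_tacs=decomp.G,
        maps=maps,
        selected_voxels=selected,
        region_tacs=region_tacs,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 1.0 if sa == sb == 0 else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _redundant_pair(decomp: NmfDecomposition, maps: ProbabilityMaps, corr_threshold: float) -> bool:
    """True if any two components look like the same tissue.

    Redundancy requires either an identical TAC peak frame, or both the
    TAC correlation and the probability-map correlation above threshold.
    """
    n = decomp.n_components
    peak_frames = np.argmax(decomp.G, axis=0)
    for i in range(n):
        for j in range(i + 1, n):
            if peak_frames[i] == peak_frames[j]:
                return True
            tac_r = _pearson(decomp.G[:, i], decomp.G[:, j])
            map_r = _pearson(maps.R[i], maps.R[j])
            if tac_r > corr_threshold and map_r > corr_threshold:
                return True
    return False


def choose_n_components(
    Zmat: VoxelTacMatrix,
    n_range: tuple[int, int] = (2, 4),
    corr_threshold: float = 0.7,
    r_threshold: float = 0.9,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[int, NmfDecomposition, ComponentSet]:
    """Select the number of identifiable components automatically.

    Decomposes with n ascending through ``n_range``.  If a decomposition
    shows a redundant component pair, the previous n is returned (with a
    warning if that happens already at the minimum).  A rank-deficiency
    failure — the noiseless-data analogue of redundancy — likewise stops
    the search at the previous n.
    """
    n_min, n_max = n_range
    if not 1 <= n_min <= n_max:
        raise ValueError("invalid n_range")
    best = None  # (n, decomp, cset)
    for n in range(n_min, n_max + 1):
        try:
            decomp, _ = unmix_voi(Zmat, n, seed=seed, max_iter=max_iter, tol=tol)
        except RankDeficiencyError:
            if best is None:
                raise
            break
        maps = relative_probability(decomp.H)
        if _redundant_pair(decomp, maps, corr_threshold):
            if best is None:
                warnings.warn(
                    f"redundant components already at n={n}; returning the "
                    "minimum model",
                    stacklevel=2,
                )
                best = (n, decomp, identify_components(Zmat, decomp, r_threshold))
            break
        best = (n, decomp, identify_components(Zmat, decomp, r_threshold))
    assert best is not None
    return best


def extract_nmf_idif(
    Zmat: VoxelTacMatrix,
    n_components: int | None = None,
    seed: int = 0,
    r_threshold: float = 0.9,
    corr_threshold: float = 0.7,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[Tac, ComponentSet]:
    """Extract the left-ventricle input function from a heart-VOI matrix.

    With ``n_components=None`` the component count is chosen automatically;
    if the chosen model yields no identifiable LV selection (too many
    components under noise), n is stepped down until one appears — the
    automated analogue of adjusting the component count by inspection.
    With a fixed ``n_components`` the given n is used as-is.  Returns the
    LV voxel-average TAC and the full labeled component set.
    """
    if n_components is None:
        n_sel, decomp, cset = choose_n_components(
            Zmat, corr_threshold=corr_threshold, r_threshold=r_threshold,
            seed=seed, max_iter=max_iter, tol=tol,
        )
        while "LV" not in cset.region_tacs and n_sel > 2:
            n_sel -= 1
            decomp, _ = unmix_voi(Zmat, n_sel, seed=seed, max_iter=max_iter, tol=tol)
            cset = identify_components(Zmat, decomp, r_threshold)
    else:
        decomp, _ = unmix_voi(Zmat, n_components, seed=seed, max_iter=max_iter, tol=tol)
        cset = identify_components(Zmat, decomp, r_threshold)
    return cset.tac("LV"), cset
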