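"""Synthetic multi-subject, multi-condition ROI time-series generator.

Emulates a four-condition within-subject resting-state study — wakefulness
(W), sedation (S), loss of consciousness (LOC) and recovery (R) — over an
atlas of ROIs grouped into eight anatomical subdivisions. The generator is
a latent factor model with a distance kernel:

* K module signals (smooth Gaussian processes) drive the ROIs assigned to
  them; cross-module leakage decays as ``exp(-d/lambda)`` with inter-ROI
  barycenter distance ``d``, so modular community structure and
  distance-dependent correlation decay coexist in the same covariance.
* A sparse backbone of strong long-range cortico-cortical "integration
  shortcuts" (built as shared pairwise factors, so the covariance stays
  positive semi-definite) keeps wakeful networks globally integrated, and
  tight spatial sub-cliques (~12 ROIs) nested inside modules carry local
  assembly coherence.
* Each condition modifies the inter-ROI couplings through an
  :class:`EffectSpec`: a global gain, additive deltas on subdivision-class
  blocks (thalamo-cortical hyperconnectivity under sedation), sign flips
  of cortico-cortical couplings targeting the shortcuts first (the
  elevated negative-edge fraction and raised path length of LOC),
  sub-clique coherence multipliers (damped in active wakefulness,
  restored in LOC and recovery: the normalized-clustering dissociation)
  and a within-module clustering multiplier.
* Subjects perturb all couplings multiplicatively (log-normal), once per
  subject and shared across that subject's four scans; on top, a per-scan
  log-normal factor on the shortcut backbone emulates session-to-session
  fluctuations of global integration.

Default effect sizes are calibrated once against the descriptive statistics
of the emulated study (median correlation about 0.2 in wakefulness with
roughly 80% of correlations in [0, 0.4]; LOC globally weakened with a 14%
negative-edge fraction; R near wakefulness with elevated clustering).
Everything is reproducible bit-for-bit from a single integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2
from scipy.ndimage import gaussian_filter1d

from .atlas import (
    CONDITIONS,
    CORTICAL,
    SUBDIVISIONS,
    ROIAtlas,
    StudyDataset,
    TimeSeriesPanel,
    ValidationError,
)

#: label usable in block deltas to mean "any cortical subdivision"
CORTEX = "Cx"

#: default subdivision proportions for a 194-ROI whole-brain parcellation
DEFAULT_FRACTIONS = {
    "Fcx": 0.27, "Tcx": 0.18, "Pcx": 0.16, "Ocx": 0.12,
    "BG": 0.07, "Thl": 0.04, "BS": 0.03, "Crbl": 0.13,
}

# per-subdivision coordinate boxes (mm), loosely MNI-sized
_BOXES = {
    "Fcx": ((-60, 60), (10, 75), (-20, 60)),
    "Tcx": ((-70, 70), (-45, 15), (-40, 5)),
    "Pcx": ((-60, 60), (-75, -25), (20, 70)),
    "Ocx": ((-55, 55), (-105, -60), (-15, 35)),
    "BG": ((-30, 30), (-15, 25), (-10, 20)),
    "Thl": ((-20, 20), (-30, 0), (-5, 15)),
    "BS": ((-12, 12), (-35, -15), (-45, -10)),
    "Crbl": ((-50, 50), (-85, -40), (-55, -15)),
}


@dataclass
class EffectSpec:
    """How one condition modifies the baseline inter-ROI couplings."""

    condition: str
    global_gain: float = 1.0
    #: additive deltas on subdivision-class blocks; ``Cx`` expands to the
    #: four cortical lobes
    block_deltas: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    #: when > 0, block deltas apply only to couplings already above this
    #: value: hyperconnectivity of established links, which shifts the
    #: unthresholded matrices (visible to the classifier) without pulling
    #: new edges into the thresholded graphs
    block_delta_floor: float = 0.0
    #: target proportion of negative edges planted by sign-flipping
    #: cortico-cortical couplings
    negative_fraction_target: float = 0.0
    #: multiplier on within-module couplings; only couplings above
    #: boost_floor are boosted (a floor above the graph-retention cutoff
    #: strengthens existing triangles without reshaping the topology)
    clustering_boost: float = 1.0
    boost_floor: float = 0.0
    #: restrict clustering_boost to pairs with at least one cortical ROI
    boost_cortical_only: bool = False
    #: multiplier on the long-range integration shortcuts (1 = unchanged)
    shortcut_boost: float = 1.0
    #: multiplier on all cross-module couplings (integration channel)
    cross_module_gain: float = 1.0
    #: multiplier on couplings within tight spatial sub-cliques (~12 ROIs):
    #: raises triangle weights (clustering) without touching the
    #: inter-module backbone that determines path length
    subclique_boost: float = 1.0
    #: loading of an extra shared factor per sub-clique (raw loading
    #: units); the PSD-safe route to elevated local clustering
    subclique_factor: float = 0.0
    #: weight-contrast exponent: positive couplings are mapped through a
    #: median-preserving power law c -> m * (c/m)**gamma, a strictly
    #: monotone transform that sharpens (gamma > 1) the strong/weak
    #: contrast without reordering any coupling
    contrast_gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.global_gain <= 0:
            raise ValidationError("global_gain must be > 0")
        if not (0 <= self.negative_fraction_target < 1):
            raise ValidationError("negative_fraction_target must be in [0, 1)")


@dataclass
class GroundTruth:
    """Generator parameters plus realized planted structure."""

    effects: dict[str, EffectSpec]
    modules: np.ndarray  # module id per ROI
    #: sub-clique id per ROI (tight spatial blocks nested inside modules)
    submodules: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    lambda_mm: float = 60.0
    noise_sd: float = 1.0
    module_loading: float = 1.0
    leak_strength: float = 1.0
    subject_sd: float = 0.15
    t_smooth: float = 1.5  # temporal Gaussian smoothing, in samples
    n_modules: int = 6
    #: long-range integration shortcuts: strong cross-module
    #: cortico-cortical couplings present in the wakeful baseline (built
    #: as shared pairwise factors, so the covariance stays PSD); the
    #: planted LOC decorrelation removes these first
    shortcut_fraction: float = 0.004
    shortcut_strength: float = 0.55
    shortcut_pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    #: SD of the per-scan log-normal factor on shortcut couplings:
    #: session-to-session fluctuation of long-range integration (vigilance
    #: drifts between scans), the dominant source of between-scan variance
    #: in path-length metrics
    shortcut_scan_sd: float = 0.5
    #: filled by simulate_study: per-condition (i, j) index arrays of
    #: sign-flipped cortico-cortical couplings
    flipped_edges: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.modules = np.asarray(self.modules, int)
        if self.modules.ndim != 1:
            raise ValidationError("modules must be a 1-D assignment vector")

    def to_json_dict(self) -> dict:
        return {
            "lambda_mm": self.lambda_mm,
            "noise_sd": self.noise_sd,
            "module_loading": self.module_loading,
            "leak_strength": self.leak_strength,
            "subject_sd": self.subject_sd,
            "n_modules": self.n_modules,
            "modules": self.modules.tolist(),
            "submodules": self.submodules.tolist(),
            "shortcut_fraction": self.shortcut_fraction,
            "shortcut_strength": self.shortcut_strength,
            "shortcut_scan_sd": self.shortcut_scan_sd,
            "shortcut_pairs": self.shortcut_pairs.tolist(),
            "effects": {
                c: {
                    "global_gain": e.global_gain,
                    "block_deltas": [[list(p), d] for p, d in e.block_deltas],
                    "negative_fraction_target": e.negative_fraction_target,
                    "clustering_boost": e.clustering_boost,
                    "boost_floor": e.boost_floor,
                    "shortcut_boost": e.shortcut_boost,
                    "cross_module_gain": e.cross_module_gain,
                    "subclique_boost": e.subclique_boost,
                    "subclique_factor": e.subclique_factor,
                    "contrast_gamma": e.contrast_gamma,
                }
                for c, e in self.effects.items()
            },
            "flipped_edges": {c: v.tolist() for c, v in self.flipped_edges.items()},
        }


def default_effects() -> dict[str, EffectSpec]:
    """The planted condition effects of the emulated study.

    During active wakefulness (W and, to a lesser degree, S) local
    assemblies are partially desynchronized (sub-clique couplings damped),
    so clustering is at its lowest relative to matched nulls. S adds
    thalamo-frontal hyperconnectivity on top. LOC globally weakens
    couplings, flips 14% of edges to negative (removing the long-range
    integration shortcuts first) and keeps its local assemblies coherent —
    elevated clustering plus elevated path length. R returns to near-W
    coupling strength with largely re-coherent local assemblies (elevated
    clustering) while its integration backbone (shortcuts, mild thalamic
    hubs) is restored, keeping path length near wakefulness level.
    """
    return {
        "W": EffectSpec("W", subclique_boost=0.55),
        "S": EffectSpec(
            "S",
            global_gain=0.96,
            block_deltas=[(("Thl", CORTEX), 0.22)],
            block_delta_floor=0.20,
            shortcut_boost=0.85,
            subclique_boost=0.55,
        ),
        "LOC": EffectSpec(
            "LOC",
            global_gain=0.70,
            negative_fraction_target=0.14,
            clustering_boost=1.45,
            boost_cortical_only=True,
            subclique_boost=1.0,  # local assemblies stay coherent
        ),
        "R": EffectSpec(
            "R",
            global_gain=0.97,
            subclique_boost=0.8,
            shortcut_boost=1.1,
            block_deltas=[(("Thl", CORTEX), 0.08)],
        ),
    }


def make_atlas(
    n_roi: int = 194,
    subdivision_fractions: dict[str, float] | None = None,
    seed: int = 0,
) -> ROIAtlas:
    """Synthetic ROI atlas with subdivision proportions and boxed coordinates.

    Subdivision counts follow largest-remainder rounding of the requested
    fractions; coordinates are drawn uniformly inside subdivision-specific
    boxes of a brain-sized volume. Deterministic given ``seed``.
    """
    if n_roi < len(SUBDIVISIONS):
        raise ValidationError(f"n_roi must be >= {len(SUBDIVISIONS)}")
    fr = dict(DEFAULT_FRACTIONS if subdivision_fractions is None else subdivision_fractions)
    total = sum(fr.get(s, 0.0) for s in SUBDIVISIONS)
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"subdivision fractions sum to {total}, expected 1")
    # largest-remainder apportionment
    quotas = np.array([fr.get(s, 0.0) * n_roi for s in SUBDIVISIONS])
    counts = np.floor(quotas).astype(int)
    remainder = n_roi - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:remainder]] += 1

    rng = np.random.default_rng(seed)
    rows = []
    rid = 0
    for s, c in zip(SUBDIVISIONS, counts):
        (x0, x1), (y0, y1), (z0, z1) = _BOXES[s]
        xyz = rng.uniform([x0, y0, z0], [x1, y1, z1], size=(c, 3))
        for k in range(c):
            rows.append((rid, f"{s}_{k:03d}", s, *np.round(xyz[k], 2)))
            rid += 1
    table = pd.DataFrame(rows, columns=["roi_id", "name", "subdivision", "x", "y", "z"])
    return ROIAtlas(table)


def make_ground_truth(
    atlas: ROIAtlas,
    effects: dict[str, EffectSpec] | None = None,
    n_modules: int = 6,
    lambda_mm: float = 60.0,
    noise_sd: float = 1.0,
    subject_sd: float = 0.15,
    seed: int = 0,
) -> GroundTruth:
    """Assign ROIs to spatially coherent modules and bundle generator params.

    Modules come from seeded k-means on barycenter coordinates, so module
    membership correlates with distance the way functional communities do.
    """
    coords = atlas.coords
    _, labels = kmeans2(coords, n_modules, minit="++", seed=seed)
    # guard: k-means can return empty clusters on degenerate geometry
    for k in range(n_modules):
        if not (labels == k).any():
            labels[np.argmax(np.bincount(labels))] = k
    # tight spatial sub-cliques (~12 ROIs) nested inside each module
    sub = np.zeros(atlas.n, int)
    next_id = 0
    for k in range(n_modules):
        idx = np.flatnonzero(labels == k)
        n_blocks = max(1, int(round(idx.size / 12)))
        if n_blocks == 1:
            sub[idx] = next_id
            next_id += 1
            continue
        _, bl = kmeans2(coords[idx], n_blocks, minit="++", seed=seed + 31 * k)
        sub[idx] = next_id + bl
        next_id += n_blocks
    truth = GroundTruth(
        effects=effects if effects is not None else default_effects(),
        modules=labels,
        submodules=sub,
        lambda_mm=lambda_mm,
        noise_sd=noise_sd,
        subject_sd=subject_sd,
        n_modules=n_modules,
    )
    # seeded choice of long-range integration shortcuts: cross-module
    # cortico-cortical pairs
    n = atlas.n
    iu, ju = np.triu_indices(n, k=1)
    cort = np.isin(atlas.subdivision, list(CORTICAL))
    eligible = np.flatnonzero(cort[iu] & cort[ju] & (labels[iu] != labels[ju]))
    n_short = min(eligible.size,
                  int(np.floor(truth.shortcut_fraction * iu.size + 0.5)))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5C]))
    # greedy pick with at most 2 shortcuts per ROI, so no ROI's variance
    # is dominated by shortcut factors
    order = rng.permutation(eligible)
    use = np.zeros(n, int)
    pairs = []
    for idx in order:
        a, b = iu[idx], ju[idx]
        if use[a] < 2 and use[b] < 2:
            pairs.append((a, b))
            use[a] += 1
            use[b] += 1
        if len(pairs) == n_short:
            break
    truth.shortcut_pairs = np.array(pairs, int).reshape(-1, 2)
    return truth


def _base_correlation(atlas: ROIAtlas, truth: GroundTruth,
                      subclique_loading: float = 0.0) -> np.ndarray:
    """Expected correlation matrix of the factor model (W = no extras).

    ``subclique_loading`` adds one shared factor per spatial sub-clique
    with that loading on its members, raising within-clique correlations
    while the covariance stays PSD by construction.
    """
    mod = truth.modules
    centroids = np.stack([atlas.coords[mod == k].mean(axis=0) for k in range(truth.n_modules)])
    d_cent = np.linalg.norm(atlas.coords[:, None, :] - centroids[None, :, :], axis=2)
    loadings = truth.leak_strength * np.exp(-d_cent / truth.lambda_mm)
    loadings[np.arange(atlas.n), mod] += truth.module_loading
    if subclique_loading > 0 and truth.submodules.size:
        n_sub = truth.submodules.max() + 1
        extra = np.zeros((atlas.n, n_sub))
        extra[np.arange(atlas.n), truth.submodules] = subclique_loading
        loadings = np.hstack([loadings, extra])
    s = loadings @ loadings.T
    var = np.diag(s).copy() + truth.noise_sd**2
    np.fill_diagonal(s, var)
    # shortcut pairs get a shared private factor driving their correlation
    # toward shortcut_strength: add a*(e_i+e_j)(e_i+e_j)^T, which is PSD
    cstar = truth.shortcut_strength
    for a, b in truth.shortcut_pairs:
        vbar = np.sqrt(s[a, a] * s[b, b])
        add = max(0.0, (cstar * vbar - s[a, b]) / (1.0 - cstar))
        s[a, b] += add
        s[b, a] = s[a, b]
        s[a, a] += add
        s[b, b] += add
    var = np.diag(s)
    corr = s / np.sqrt(np.outer(var, var))
    np.fill_diagonal(corr, 1.0)
    return corr


def _expand_block(pair: tuple[str, str], subdiv: np.ndarray) -> np.ndarray:
    """Boolean N x N mask of ROI pairs whose subdivisions match the block."""
    def member(label: str) -> np.ndarray:
        if label == CORTEX:
            return np.isin(subdiv, list(CORTICAL))
        return subdiv == label

    a, b = member(pair[0]), member(pair[1])
    mask = np.outer(a, b) | np.outer(b, a)
    np.fill_diagonal(mask, False)
    return mask


def _apply_effect(
    base: np.ndarray,
    spec: EffectSpec,
    atlas: ROIAtlas,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (condition coupling matrix, flipped (i,j) pairs)."""
    c = base.copy()
    off = ~np.eye(len(c), dtype=bool)
    c[off] *= spec.global_gain
    for pair, delta in spec.block_deltas:
        mask = _expand_block(pair, atlas.subdivision) & off
        if spec.block_delta_floor > 0:
            mask &= c > spec.block_delta_floor
        c[mask] += delta
    same_module = (truth.modules[:, None] == truth.modules[None, :]) & off
    within = same_module.copy()
    if spec.boost_floor > 0:
        within &= c > spec.boost_floor
    if spec.boost_cortical_only:
        cort_any = np.isin(atlas.subdivision, list(CORTICAL))
        within &= cort_any[:, None] | cort_any[None, :]
    c[within] *= spec.clustering_boost
    if spec.cross_module_gain != 1.0:
        cross = ~same_module & off
        c[cross] *= spec.cross_module_gain
    if spec.subclique_boost != 1.0 and truth.submodules.size:
        same_sub = (truth.submodules[:, None] == truth.submodules[None, :]) & off
        # soft cap keeps boosted blocks clear of the unit ceiling, where
        # the PSD repair would otherwise crush the planted structure
        boosted = np.minimum(c[same_sub] * spec.subclique_boost,
                             np.maximum(c[same_sub], 0.92))
        c[same_sub] = boosted
    if spec.shortcut_boost != 1.0 and truth.shortcut_pairs.size:
        si, sj = truth.shortcut_pairs.T
        c[si, sj] *= spec.shortcut_boost
        c[sj, si] = c[si, sj]
    if spec.contrast_gamma != 1.0:
        pos = off & (c > 0)
        m = np.median(c[pos])
        c[pos] = m * (c[pos] / m) ** spec.contrast_gamma

    flipped = np.empty((0, 2), dtype=int)
    if spec.negative_fraction_target > 0:
        n = len(c)
        m = n * (n - 1) // 2
        n_flip = int(np.floor(spec.negative_fraction_target * m + 0.5))
        cort = np.isin(atlas.subdivision, list(CORTICAL))
        iu, ju = np.triu_indices(n, k=1)
        cc = cort[iu] & cort[ju]
        candidates = np.flatnonzero(cc)
        if n_flip > candidates.size:
            raise ValidationError(
                f"cannot plant {n_flip} negative edges: only {candidates.size} "
                "cortico-cortical pairs available"
            )
        # flips take the long-range integration shortcuts first, then the
        # remaining cross-module cortico-cortical couplings: planted
        # decorrelation removes exactly the wakeful shortcuts, raising
        # path length while within-module structure stays intact
        flat = {i * len(c) + j for i, j in truth.shortcut_pairs}
        is_short = np.array([(a * len(c) + b) in flat for a, b in zip(iu, ju)])
        cross = truth.modules[iu] != truth.modules[ju]
        short_idx = np.flatnonzero(cc & is_short)
        rest = candidates[cross[candidates] & ~is_short[candidates]]
        # beyond the shortcuts, a tranche of the strongest cross-module
        # couplings decorrelates (the hypoconnectivity that classifies the
        # state), then the remainder comes from the weaker half, which
        # keeps the planted matrix close to PSD
        n_short_take = min(n_flip, short_idx.size)
        n_left = n_flip - n_short_take
        order = np.argsort(np.abs(c[iu[rest], ju[rest]]), kind="stable")
        weak = rest[order[: rest.size // 2]]
        strong = rest[order[max(0, rest.size - rest.size // 5):]]
        n_strong = min(400, n_left, strong.size)
        strong_take = rng.choice(strong, size=n_strong, replace=False)
        n_weak = n_left - n_strong
        pool = weak if weak.size >= n_weak else rest
        weak_take = rng.choice(np.setdiff1d(pool, strong_take),
                               size=n_weak, replace=False)
        chosen = np.concatenate([short_idx[:n_short_take], strong_take,
                                 weak_take])
        fi, fj = iu[chosen], ju[chosen]
        c[fi, fj] *= -1
        c[fj, fi] *= -1
        flipped = np.column_stack([fi, fj])
    np.clip(c, -0.97, 0.97, out=c)
    np.fill_diagonal(c, 1.0)
    return c, flipped


def _nearest_correlation(c: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Repair a coupling matrix to positive semi-definite by eigenvalue clipping."""
    w, v = np.linalg.eigh(c)
    if w.min() >= 0:
        return c
    warnings.warn(
        "coupling matrix not positive semi-definite after effects; "
        "repaired by eigenvalue clipping",
        RuntimeWarning,
        stacklevel=2,
    )
    w = np.clip(w, floor, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    repaired = (repaired + repaired.T) / 2
    np.fill_diagonal(repaired, 1.0)
    return repaired


def condition_couplings(
    atlas: ROIAtlas, truth: GroundTruth, seed: int = 0
) -> dict[str, np.ndarray]:
    """Expected (group-level) correlation matrix per condition."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0]))
    base = _base_correlation(atlas, truth)
    out = {}
    for cond in CONDITIONS:
        spec = truth.effects[cond]
        start = base
        if spec.subclique_factor > 0:
            start = _base_correlation(atlas, truth,
                                      subclique_loading=spec.subclique_factor)
        c, flipped = _apply_effect(start, spec, atlas, truth, rng)
        truth.flipped_edges[cond] = flipped
        out[cond] = _nearest_correlation(c)
    return out


def _smooth_unit_noise(rng: np.random.Generator, t: int, n: int, sigma: float) -> np.ndarray:
    """T x N temporally smoothed, column-standardized Gaussian innovations."""
    f = rng.standard_normal((t + 8, n))
    if sigma > 0:
        f = gaussian_filter1d(f, sigma=sigma, axis=0)
    f = f[4 : 4 + t]
    f = f - f.mean(axis=0)
    sd = f.std(axis=0)
    sd[sd == 0] = 1.0
    return f / sd


def simulate_study(
    atlas: ROIAtlas,
    truth: GroundTruth,
    n_subjects: int = 12,
    n_timepoints: int = 196,
    seed: int = 0,
    tr: float = 2.46,
) -> tuple[StudyDataset, GroundTruth]:
    """Generate a balanced study: ``n_subjects`` x 4 conditions of T x N panels.

    Per subject-condition, the target correlation matrix is the condition
    coupling matrix times that subject's log-normal coupling perturbation
    (shared across the subject's four scans), PSD-repaired, and sampled by
    mixing smooth unit-variance innovations through its matrix square root.
    """
    if n_subjects < 2:
        raise ValidationError("n_subjects must be >= 2")
    if n_timepoints < 20:
        raise ValidationError("n_timepoints must be >= 20")
    couplings = condition_couplings(atlas, truth, seed=seed)
    n = atlas.n
    off = ~np.eye(n, dtype=bool)
    ss = np.random.SeedSequence([seed, 0x5D])
    subj_rngs = [np.random.default_rng(s) for s in ss.spawn(n_subjects)]
    panels: dict[tuple[str, str], TimeSeriesPanel] = {}
    for si in range(n_subjects):
        rng = subj_rngs[si]
        subject = f"sub{si + 1:02d}"
        # symmetric log-normal perturbation of couplings, one draw per subject
        logp = rng.normal(0.0, truth.subject_sd, size=(n, n))
        pert = np.exp((logp + logp.T) / 2)
        for cond in CONDITIONS:
            target = couplings[cond].copy()
            target[off] *= pert[off]
            if truth.shortcut_pairs.size and truth.shortcut_scan_sd > 0:
                # per-scan integration state scales the shortcut backbone
                sfac = np.exp(rng.normal(0.0, truth.shortcut_scan_sd))
                si, sj = truth.shortcut_pairs.T
                target[si, sj] *= sfac
                target[sj, si] = target[si, sj]
            np.clip(target, -0.97, 0.97, out=target)
            np.fill_diagonal(target, 1.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                target = _nearest_correlation(target)
            w, v = np.linalg.eigh(target)
            mix = v * np.sqrt(np.clip(w, 0.0, None))
            f = _smooth_unit_noise(rng, n_timepoints, n, truth.t_smooth)
            data = f @ mix.T
            panels[(subject, cond)] = TimeSeriesPanel(subject, cond, data, tr=tr)
    return StudyDataset(atlas, panels), truth
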