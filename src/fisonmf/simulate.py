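"""Seeded generator of SV-MRS-like datasets with known ground truth.

The generator emulates the statistical structure of multi-center brain-tumor
spectroscopy cohorts: every case is a convex combination of two constituent
tissue signatures — *actively proliferating* tissue (high choline at
~3.21 ppm, visible creatine/NAA/myo-inositol) and *necrotic* tissue (high
mobile lipids and lactate at ~1.3 and ~0.9 ppm) — plus i.i.d. Gaussian
noise, followed by unit-length (UL2) normalization.  Three class archetypes
mirror low-grade astrocytoma (mostly proliferating, homogeneous),
glioblastoma (heterogeneous mixture of both constituents) and metastasis
(dominantly necrotic).  In long-echo-time (LTE) mode the lactate doublet is
inverted, producing the negative peaks real LTE spectra show; short-echo
(STE) prototypes are element-wise non-negative.

Peaks are Gaussian lineshapes by default (Lorentzian optional); the target
is qualitative fidelity of peak positions and sign patterns, not a physical
MR simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import PpmAxis, SpectrumDataset, ul2_normalize

__all__ = [
    "PeakSpec",
    "ClassPrototype",
    "SyntheticGroundTruth",
    "make_prototype_sources",
    "generate_dataset",
    "inject_outliers",
]

# Default class sizes mirror the modeled cohorts (STE: 22/86/38, LTE: 20/78/31)
DEFAULT_CLASS_SIZES = {
    "STE": {"A2": 22, "GL": 86, "ME": 38},
    "LTE": {"A2": 20, "GL": 78, "ME": 31},
}


@dataclass(frozen=True)
class PeakSpec:
    """One metabolite resonance: center/width in ppm, signed amplitude."""

    center: float
    width: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak width must be positive")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError("shape must be 'gaussian' or 'lorentzian'")

    def evaluate(self, ppm: np.ndarray) -> np.ndarray:
        x = (np.asarray(ppm, dtype=float) - self.center) / self.width
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-0.5 * x**2)
        return self.amplitude / (1.0 + x**2)


def _signature(axis: PpmAxis, peaks: list[PeakSpec]) -> np.ndarray:
    sig = np.zeros(len(axis))
    for pk in peaks:
        sig += pk.evaluate(axis.values)
    return sig


# Constituent tissue signatures as peak lists.  Amplitudes are relative;
# signatures are UL2-normalized after evaluation on the axis.
def _proliferating_peaks() -> list[PeakSpec]:
    return [
        PeakSpec(3.21, 0.035, 1.00),   # total choline
        PeakSpec(3.55, 0.040, 0.45),   # myo-inositol / glycine
        PeakSpec(3.03, 0.030, 0.40),   # creatine
        PeakSpec(3.93, 0.030, 0.20),   # creatine (CH2)
        PeakSpec(2.01, 0.040, 0.35),   # NAA (residual)
        PeakSpec(1.29, 0.060, 0.08),   # faint mobile lipids
    ]


def _necrotic_peaks(te_mode: str) -> list[PeakSpec]:
    # short-T2 mobile-lipid signals fade at long echo time, where the
    # J-modulated lactate doublet appears inverted
    lipid_scale = 0.35 if te_mode == "LTE" else 1.0
    lactate_amp = -0.90 if te_mode == "LTE" else 0.50
    return [
        PeakSpec(1.29, 0.070, 1.00 * lipid_scale),   # mobile lipids (CH2)
        PeakSpec(0.90, 0.070, 0.55 * lipid_scale),   # mobile lipids (CH3)
        PeakSpec(1.31, 0.020, lactate_amp),          # lactate doublet
        PeakSpec(1.36, 0.020, lactate_amp),
        PeakSpec(3.21, 0.035, 0.18),                 # residual choline
        PeakSpec(3.03, 0.030, 0.10),
    ]


@dataclass(frozen=True)
class ClassPrototype:
    """A class archetype: constituent signatures and a Dirichlet mixing law.

    ``alpha`` parameterizes the Dirichlet distribution over constituents
    from which per-case mixing proportions are drawn; its normalized value
    is the class's mean constituent composition.
    """

    name: str
    constituents: np.ndarray          # d x k_true, UL2-normalized columns
    alpha: np.ndarray                 # Dirichlet concentration, length k_true
    constituent_names: tuple[str, ...] = ("proliferating", "necrotic")

    @property
    def mean_weights(self) -> np.ndarray:
        return self.alpha / self.alpha.sum()

    @property
    def mean_spectrum(self) -> np.ndarray:
        return ul2_normalize(self.constituents @ self.mean_weights)


def make_prototype_sources(
    axis: PpmAxis | None = None, te_mode: str = "STE"
) -> list[ClassPrototype]:
    """Build the three class archetypes on a ppm axis.

    Returns A2-like (low-grade, dominated by the proliferating signature),
    GL-like (heterogeneous mix of proliferating and necrotic constituents)
    and ME-like (dominantly necrotic).  STE constituents are element-wise
    non-negative; LTE constituents carry an inverted lactate doublet.
    """
    if axis is None:
        axis = PpmAxis.default()
    if te_mode not in ("STE", "LTE"):
        raise ValueError("te_mode must be 'STE' or 'LTE'")
    prolif = ul2_normalize(_signature(axis, _proliferating_peaks()))
    necro = ul2_normalize(_signature(axis, _necrotic_peaks(te_mode)))
    constituents = np.column_stack([prolif, necro])
    # Dirichlet concentrations: total magnitude controls within-class
    # spread (A2 tight, GL loose/heterogeneous, ME fairly tight).
    return [
        ClassPrototype("A2", constituents, np.array([27.0, 3.0])),
        ClassPrototype("GL", constituents, np.array([4.0, 6.0])),
        ClassPrototype("ME", constituents, np.array([3.0, 17.0])),
    ]


@dataclass
class SyntheticGroundTruth:
    """What the generator knows: constituent sources, mixing, alterations."""

    sources: np.ndarray               # d x k_true constituent signatures
    proportions: np.ndarray           # k_true x n, columns sum to 1
    labels: np.ndarray
    noise_sd: float
    altered_columns: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int)
    )


def generate_dataset(
    prototypes: list[ClassPrototype],
    n_per_class: dict[str, int],
    noise_sd: float = 0.01,
    overlap: float = 0.0,
    seed: int | None = None,
    axis: PpmAxis | None = None,
    te_mode: str = "STE",
) -> tuple[SpectrumDataset, SyntheticGroundTruth]:
    """Draw a labeled synthetic dataset with known mixing ground truth.

    Each case of class ``c`` mixes the constituent signatures with
    proportions drawn from the class's Dirichlet; ``overlap`` in [0, 1]
    pulls every class's mean composition toward the average of the other
    classes, emulating cohorts whose class-mean spectra are highly
    correlated.  Gaussian noise of standard deviation ``noise_sd`` is added
    before UL2 normalization, so normalization acts as it does on real data.
    """
    if not prototypes:
        raise ValueError("prototype list is empty")
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    by_name = {p.name: p for p in prototypes}
    for cls, cnt in n_per_class.items():
        if cls not in by_name:
            raise KeyError(f"no prototype for class {cls!r}")
        if cnt < 1:
            raise ValueError("class counts must be >= 1")
    if axis is None:
        axis = PpmAxis.default()
    rng = np.random.default_rng(seed)

    classes = [c for c in n_per_class]  # caller's order
    mean_w = {c: by_name[c].mean_weights for c in classes}
    cols, labels, props = [], [], []
    for cls in classes:
        proto = by_name[cls]
        others = [mean_w[o] for o in classes if o != cls]
        target = (
            mean_w[cls]
            if not others
            else (1 - overlap) * mean_w[cls] + overlap * np.mean(others, axis=0)
        )
        # keep the Dirichlet's total concentration, move its mean
        alpha = np.maximum(target * proto.alpha.sum(), 1e-3)
        for _ in range(n_per_class[cls]):
            w = rng.dirichlet(alpha)
            x = proto.constituents @ w
            if noise_sd > 0:
                x = x + rng.normal(0.0, noise_sd, size=x.shape)
            cols.append(ul2_normalize(x))
            labels.append(cls)
            props.append(w)

    X = np.column_stack(cols)
    ds = SpectrumDataset(X, axis, np.array(labels, dtype=object), te_mode)
    gt = SyntheticGroundTruth(
        sources=prototypes[0].constituents.copy(),
        proportions=np.array(props).T,
        labels=ds.labels.copy(),
        noise_sd=noise_sd,
    )
    return ds, gt


def generate_pure_dataset(
    prototypes: list[ClassPrototype],
    n_per_class: dict[str, int],
    axis: PpmAxis | None = None,
    te_mode: str = "STE",
) -> tuple[SpectrumDataset, SyntheticGroundTruth]:
    """Degenerate generator: every case equals its class's mean composition
    exactly (no noise, no sampling).  Useful for exact-recovery checks."""
    if not prototypes:
        raise ValueError("prototype list is empty")
    if axis is None:
        axis = PpmAxis.default()
    by_name = {p.name: p for p in prototypes}
    cols, labels, props = [], [], []
    for cls, cnt in n_per_class.items():
        proto = by_name[cls]
        w = proto.mean_weights
        x = ul2_normalize(proto.constituents @ w)
        for _ in range(cnt):
            cols.append(x)
            labels.append(cls)
            props.append(w)
    ds = SpectrumDataset(
        np.column_stack(cols), axis, np.array(labels, dtype=object), te_mode
    )
    gt = SyntheticGroundTruth(
        prototypes[0].constituents.copy(), np.array(props).T, ds.labels.copy(), 0.0
    )
    return ds, gt


def inject_outliers(
    dataset: SpectrumDataset,
    ground_truth: SyntheticGroundTruth,
    class_name: str,
    fraction: float,
    seed: int | None = None,
) -> tuple[SpectrumDataset, SyntheticGroundTruth]:
    """Make a fraction of one class atypical while keeping its labels.

    ``round(fraction * class size)`` randomly chosen members of the class
    have their constituent proportions reversed (a proliferating-dominated
    case becomes necrotic-dominated and vice versa) and their spectra
    regenerated noise-free from the reversed mix.  The returned ground
    truth records which columns were altered.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    labels = dataset.labels.astype(str)
    members = np.flatnonzero(labels == str(class_name))
    if members.size == 0:
        raise KeyError(f"class {class_name!r} not present")
    rng = np.random.default_rng(seed)
    n_alter = int(round(fraction * members.size))
    altered = np.sort(rng.choice(members, size=n_alter, replace=False))

    X = dataset.X.copy()
    props = ground_truth.proportions.copy()
    for j in altered:
        props[:, j] = props[::-1, j]  # opposite constituent pattern
        X[:, j] = ul2_normalize(ground_truth.sources @ props[:, j])
    ds = SpectrumDataset(
        X, dataset.axis, dataset.labels.copy(), dataset.te_mode, dataset.case_ids.copy()
    )
    gt = SyntheticGroundTruth(
        ground_truth.sources.copy(),
        props,
        ground_truth.labels.copy(),
        ground_truth.noise_sd,
        altered_columns=altered,
    )
    return ds, gt
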