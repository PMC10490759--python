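"""Synthetic interfered Raman spectra.

Emulates a database of liquid chemicals measured inside small glass bottles:
each chemical class is a fixed set of Lorentzian Raman bands; every
measurement adds the vessel's own signature (bands concentrated around
1000-2000 cm^-1 plus a broad fluorescence background) scaled by a random
factor whose distribution depends on the detection posture. Probing through
the bottle bottom picks up little glass signal; upright and side geometries
pick up a lot — often more than the sample's strongest band. Laser power and
integration time vary between measurements, modelled as a multiplicative
intensity scale, and detector noise is additive Gaussian. Each rendered
spectrum is min-max normalized to [0, 1], matching the acquisition pipeline.

The default dataset is 32 classes x 50 spectra (1600 total) on the 2068-point
grid, split near-equally over the three postures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DEFAULT_GRID, POSTURES, AxisGrid, SpectraDataset, Spectrum, min_max_normalize

__all__ = [
    "PeakSpec",
    "ClassSignature",
    "VesselInterference",
    "PostureModel",
    "NoiseModel",
    "GeneratorConfig",
    "make_class_signatures",
    "default_vessel",
    "lorentzian_profile",
    "render_spectrum",
    "generate_dataset",
]


@dataclass(frozen=True)
class PeakSpec:
    """One Lorentzian band: centre (cm^-1), FWHM (cm^-1), relative amplitude."""

    center: float
    fwhm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class ClassSignature:
    """The fixed band set of one chemical class.

    The primary peak (largest amplitude) is what a naive peak-matching
    identifier would latch onto; interference is calibrated against it.
    """

    class_id: str
    peaks: tuple[PeakSpec, ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("a signature needs at least one peak")

    @property
    def primary(self) -> PeakSpec:
        return max(self.peaks, key=lambda p: p.amplitude)


@dataclass(frozen=True)
class VesselInterference:
    """The bottle material's contribution: glass bands plus fluorescence.

    ``baseline_coeffs`` are low-order polynomial coefficients (in a [0, 1]
    normalized wavenumber coordinate) for the broad fluorescence background.
    At least one band must sit in the 1000-2000 cm^-1 region where glass
    interference concentrates.
    """

    peaks: tuple[PeakSpec, ...]
    baseline_coeffs: tuple[float, ...] = (0.3, 0.2, -0.3)

    def __post_init__(self) -> None:
        if not any(1000.0 <= p.center <= 2000.0 for p in self.peaks):
            raise ValueError("vessel interference needs a peak in 1000-2000 cm^-1")


@dataclass(frozen=True)
class PostureModel:
    """Lognormal interference-scale distributions per posture.

    Parameters are (median, sigma) of the interference amplitude relative to
    the class's primary peak. Bottom probing must be the cleanest geometry,
    and upright interference can exceed the primary peak (scale > 1 with
    non-negligible probability), as observed in practice.
    """

    upright: tuple[float, float] = (0.9, 0.4)
    side: tuple[float, float] = (0.8, 0.4)
    bottom: tuple[float, float] = (0.15, 0.4)

    def __post_init__(self) -> None:
        if not (self.bottom[0] < self.upright[0] and self.bottom[0] < self.side[0]):
            raise ValueError("bottom interference must be weakest")

    @classmethod
    def high_interference(cls) -> "PostureModel":
        """A harsh measurement campaign: upright/side interference medians
        above the primary peak (1.5 / 1.3), bottom still cleanest (0.3)."""
        return cls(upright=(1.5, 0.5), side=(1.3, 0.5), bottom=(0.3, 0.5))

    def params(self, posture: str) -> tuple[float, float]:
        return getattr(self, posture)

    def draw_scale(self, posture: str, rng: np.random.Generator) -> float:
        median, sigma = self.params(posture)
        return float(median * np.exp(sigma * rng.standard_normal()))


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise sd (relative to the primary peak) and the
    multiplicative intensity-scale range emulating laser power / integration
    time variation."""

    additive_sd: float = 0.01
    scale_range: tuple[float, float] = (0.5, 1.5)

    def __post_init__(self) -> None:
        if self.additive_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not (0 < self.scale_range[0] <= self.scale_range[1]):
            raise ValueError("scale range must be positive and ordered")


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything that defines a synthetic database."""

    n_classes: int = 32
    spectra_per_class: int = 50
    grid: AxisGrid = DEFAULT_GRID
    peak_count_range: tuple[int, int] = (4, 12)
    posture_model: PostureModel = field(default_factory=PostureModel)
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    rng_seed: int = 0


def lorentzian_profile(wavenumbers: np.ndarray, peaks: tuple[PeakSpec, ...]) -> np.ndarray:
    """Sum of Lorentzian bands evaluated on a wavenumber axis."""
    out = np.zeros_like(wavenumbers, dtype=float)
    for p in peaks:
        gamma = p.fwhm / 2.0
        out += p.amplitude * gamma**2 / ((wavenumbers - p.center) ** 2 + gamma**2)
    return out


def make_class_signatures(
    n_classes: int,
    rng_seed: int = 0,
    peak_count_range: tuple[int, int] = (4, 12),
    grid: AxisGrid = DEFAULT_GRID,
    fwhm_range: tuple[float, float] = (5.0, 60.0),
    min_separation: float = 30.0,
    max_tries: int = 10_000,
) -> list[ClassSignature]:
    """Draw ``n_classes`` distinct class signatures, deterministically per seed.

    Primary-peak centres are rejection-sampled to sit at least two FWHMs away
    from every other class's primary, so no two classes collapse onto the same
    strongest band; within a class, peak centres keep ``min_separation`` so
    overlapping tails cannot displace the primary maximum.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    lo, hi = peak_count_range
    if not (1 <= lo <= hi):
        raise ValueError("bad peak_count_range")
    rng = np.random.default_rng(rng_seed)
    margin = 2 * fwhm_range[1]
    left, right = grid.start + margin, grid.stop - margin
    if right <= left:
        raise ValueError("grid too small to place peaks")

    primary_centers: list[float] = []
    primary_fwhms: list[float] = []
    signatures: list[ClassSignature] = []
    for k in range(n_classes):
        for attempt in range(max_tries):
            # fwhm is redrawn with the centre: a single wide-band draw must
            # not dead-end placement on a crowded axis
            fwhm_p = rng.uniform(*fwhm_range)
            c = rng.uniform(left, right)
            if all(
                abs(c - c0) >= 2 * max(fwhm_p, f0)
                for c0, f0 in zip(primary_centers, primary_fwhms)
            ):
                break
        else:
            raise ValueError(
                f"could not place a distinct primary peak for class {k}: grid too "
                "small for the requested number of classes"
            )
        primary_centers.append(c)
        primary_fwhms.append(fwhm_p)

        n_peaks = int(rng.integers(lo, hi + 1))
        peaks = [PeakSpec(c, fwhm_p, 1.0)]
        centers = [c]
        for _ in range(n_peaks - 1):
            for attempt in range(max_tries):
                cs = rng.uniform(left, right)
                if all(abs(cs - c0) >= min_separation for c0 in centers):
                    break
            else:
                break  # grid saturated with secondary peaks; keep what fits
            centers.append(cs)
            peaks.append(
                PeakSpec(cs, rng.uniform(*fwhm_range), rng.uniform(0.15, 0.6))
            )
        signatures.append(ClassSignature(f"class_{k:02d}", tuple(peaks)))
    return signatures


def default_vessel(rng_seed: int = 12345) -> VesselInterference:
    """The shared bottle signature: one material for the whole database.

    Glass bands concentrated in 1000-2000 cm^-1 plus one weaker band outside,
    over a gentle fluorescence background.
    """
    rng = np.random.default_rng(rng_seed)
    peaks = [
        PeakSpec(rng.uniform(1000, 2000), rng.uniform(25.0, 90.0), rng.uniform(0.5, 1.0))
        for _ in range(4)
    ]
    peaks.append(PeakSpec(rng.uniform(400, 900), rng.uniform(25.0, 90.0), 0.3))
    return VesselInterference(tuple(peaks))


def render_spectrum(
    signature: ClassSignature,
    posture: str,
    vessel: VesselInterference,
    noise: NoiseModel,
    rng: np.random.Generator,
    posture_model: PostureModel | None = None,
    grid: AxisGrid = DEFAULT_GRID,
    interference_scale: float | None = None,
) -> Spectrum:
    """Render one labelled measurement of ``signature`` in ``posture``.

    intensity = sample bands
              + scale(posture) * (vessel bands + fluorescence baseline)
              + Gaussian noise,
    all multiplied by a random intensity factor, clipped at zero, then min-max
    normalized. ``interference_scale`` overrides the posture draw (used to
    switch interference off or probe the posture model).
    """
    if posture not in POSTURES:
        raise ValueError(f"unknown posture {posture!r}")
    pm = posture_model if posture_model is not None else PostureModel()
    if interference_scale is None:
        interference_scale = pm.draw_scale(posture, rng)
    w = grid.wavenumbers
    sample = lorentzian_profile(w, signature.peaks)
    glass = lorentzian_profile(w, vessel.peaks)
    t = (w - grid.start) / (grid.stop - grid.start)
    baseline = np.polyval(vessel.baseline_coeffs[::-1], t)
    primary_amp = signature.primary.amplitude
    v = sample + interference_scale * primary_amp * (glass + baseline)
    v = v + rng.normal(0.0, noise.additive_sd * primary_amp, size=w.shape)
    v = v * rng.uniform(*noise.scale_range)
    v = np.clip(v, 0.0, None)
    v = min_max_normalize(v)
    return Spectrum(grid, v, label=signature.class_id, posture=posture)


def _posture_counts(spectra_per_class: int) -> dict[str, int]:
    """Near-equal split of one class's spectra over the three postures."""
    base = spectra_per_class // 3
    rem = spectra_per_class % 3
    counts = {p: base for p in POSTURES}
    for p in POSTURES[:rem]:
        counts[p] += 1
    return counts


def generate_dataset(
    n_classes: int = 32,
    spectra_per_class: int = 50,
    rng_seed: int = 0,
    grid: AxisGrid = DEFAULT_GRID,
    posture_model: PostureModel | None = None,
    noise_model: NoiseModel | None = None,
    peak_count_range: tuple[int, int] = (4, 12),
    signatures: list[ClassSignature] | None = None,
    vessel: VesselInterference | None = None,
) -> SpectraDataset:
    """Generate the full synthetic database, deterministic per seed.

    Defaults mirror the emulated acquisition campaign: 32 classes x 50
    spectra = 1600 measurements, each class observed in all three postures
    (near-equal thirds), on the 2068-point grid.
    """
    if n_classes < 1 or spectra_per_class < 1:
        raise ValueError("need at least one class and one spectrum per class")
    if spectra_per_class < 3:
        raise ValueError("spectra_per_class must cover all three postures")
    pm = posture_model if posture_model is not None else PostureModel()
    nm = noise_model if noise_model is not None else NoiseModel()
    ss = np.random.SeedSequence(rng_seed)
    sig_seed, render_seed = (int(s) % (2**31) for s in ss.generate_state(2))
    if signatures is None:
        signatures = make_class_signatures(
            n_classes, rng_seed=sig_seed, peak_count_range=peak_count_range, grid=grid
        )
    elif len(signatures) != n_classes:
        raise ValueError("signatures length does not match n_classes")
    if vessel is None:
        vessel = default_vessel()

    rng = np.random.default_rng(render_seed)
    counts = _posture_counts(spectra_per_class)
    rows, labels, postures = [], [], []
    for sig in signatures:
        for posture in POSTURES:
            for _ in range(counts[posture]):
                sp = render_spectrum(
                    sig, posture, vessel, nm, rng, posture_model=pm, grid=grid
                )
                rows.append(sp.intensities)
                labels.append(sig.class_id)
                postures.append(posture)
    return SpectraDataset(
        grid,
        np.asarray(rows, dtype=np.float32),
        np.asarray(labels),
        [s.class_id for s in signatures],
        np.asarray(postures),
    )
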