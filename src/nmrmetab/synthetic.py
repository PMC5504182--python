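"""Synthetic 1H-NMR study generator with known ground truth.

Simulates the digitized spectra of a multi-group tissue-extract metabolomics
study: each sample is a Lorentzian mixture of library metabolites whose
concentrations vary log-normally around group means, plus a smooth baseline,
per-metabolite chemical-shift jitter (pH-type drift) and additive Gaussian
noise.  The default library carries the 35 metabolites quantified in mouse
intestine extracts, with resonance positions taken from standard reference
values (HMDB-style assignments), and the built-in study design plants the
published intestine fold changes for a control / model / two-treatment
design with unbalanced group sizes (7/16/12/9).

Because downstream constant-sum normalization is only unbiased when the
expected total spectral area is the same in every group, the generator also
simulates an "unassigned signal" pool (real spectra contain many resonances
beyond the assigned set) whose group level balances the assigned-metabolite
total.  This reproduces the statistical structure the analysis assumes; see
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SpectraSet

__all__ = [
    "Multiplet",
    "MetaboliteLibrary",
    "StudyDesign",
    "make_default_library",
    "default_reference_abundances",
    "intestine_effect_table",
    "intestine_design",
    "lorentzian",
    "default_axis",
    "simulate_spectrum",
    "simulate_study",
]

DEFAULT_HWHM = 0.002  # ppm, half-width at half-maximum of a tissue-extract line
DEFAULT_PPM_RANGE = (0.5, 9.5)
DEFAULT_N_POINTS = 8192


@dataclass(frozen=True)
class Multiplet:
    """One resonance of a metabolite: center shift, relative weight, half-width."""

    center: float  # ppm
    weight: float  # fraction of the metabolite's total integral
    hwhm: float = DEFAULT_HWHM  # ppm


@dataclass
class MetaboliteLibrary:
    """Named metabolites, each a list of multiplets whose weights sum to 1."""

    entries: dict[str, list[Multiplet]]
    ppm_range: tuple[float, float] = DEFAULT_PPM_RANGE

    def __post_init__(self) -> None:
        lo, hi = self.ppm_range
        for name, mult in self.entries.items():
            if not mult:
                raise ValueError(f"metabolite {name!r} has no multiplets")
            total = sum(m.weight for m in mult)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"multiplet weights of {name!r} sum to {total}, expected 1"
                )
            for m in mult:
                if not (lo <= m.center <= hi):
                    raise ValueError(
                        f"{name!r} multiplet at {m.center} ppm outside window "
                        f"[{lo}, {hi}]"
                    )
                if m.hwhm <= 0:
                    raise ValueError(f"{name!r} has non-positive half-width")

    @property
    def names(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def multiplet_centers(self) -> pd.DataFrame:
        rows = [
            (name, m.center, m.weight, m.hwhm)
            for name, mult in self.entries.items()
            for m in mult
        ]
        return pd.DataFrame(rows, columns=["metabolite", "center_ppm", "weight", "hwhm"])


def _mk(pairs, hwhm=DEFAULT_HWHM) -> list[Multiplet]:
    return [Multiplet(center=c, weight=w, hwhm=hwhm) for c, w in pairs]


# Resonance positions are reference-derived (standard 1H shifts in D2O,
# pH ~7.4); crowded regions (BCAA methyls, Cr/PCr, choline head-groups,
# sugar CH envelope) are kept crowded on purpose -- the binning and the
# nearest-resonance aggregation have to cope with that, as in real spectra.
_INTESTINE_LIBRARY: dict[str, list[tuple[float, float]]] = {
    "Isoleucine": [(0.94, 0.45), (1.01, 0.35), (3.67, 0.20)],
    "Leucine": [(0.96, 0.55), (1.71, 0.45)],
    "Valine": [(0.99, 0.40), (1.04, 0.40), (3.61, 0.20)],
    "Lactate": [(1.33, 0.75), (4.12, 0.25)],
    "Alanine": [(1.48, 0.75), (3.79, 0.25)],
    "Lysine": [(1.73, 0.35), (1.89, 0.25), (3.01, 0.40)],
    "Acetate": [(1.92, 1.00)],
    "Glutamate": [(2.08, 0.50), (2.34, 0.50)],
    "Glutamine": [(2.14, 0.50), (2.45, 0.50)],
    "Methionine": [(2.18, 0.50), (2.64, 0.50)],
    "Succinate": [(2.41, 1.00)],
    "Aspartate": [(2.68, 0.60), (2.81, 0.40)],
    "Glutathione": [(2.55, 0.40), (2.95, 0.40), (4.56, 0.20)],
    "Dimethylamine": [(2.72, 1.00)],
    "Creatine": [(3.04, 0.60), (3.93, 0.40)],
    "PCr": [(3.05, 0.60), (3.95, 0.40)],
    "Choline": [(3.20, 1.00)],
    "OPC": [(3.22, 0.70), (4.17, 0.30)],
    "Betaine": [(3.27, 0.75), (3.90, 0.25)],
    "Taurine": [(3.25, 0.50), (3.42, 0.50)],
    "Glucose": [(5.23, 0.15), (4.65, 0.15), (3.47, 0.40), (3.72, 0.30)],
    "Maltose": [(5.41, 0.35), (3.84, 0.65)],
    "Glycine": [(3.56, 1.00)],
    "Inosine": [(8.35, 0.30), (8.24, 0.30), (6.10, 0.40)],
    "Uracil": [(5.80, 0.50), (7.54, 0.50)],
    "Uridine": [(5.90, 0.50), (7.87, 0.50)],
    "Fumarate": [(6.52, 1.00)],
    "Tyrosine": [(6.90, 0.50), (7.19, 0.50)],
    "Histidine": [(7.09, 0.50), (7.91, 0.50)],
    "Phenylalanine": [(7.33, 0.40), (7.42, 0.60)],
    "Hypoxanthine": [(8.19, 0.50), (8.21, 0.50)],
    "Nicotinurate": [(8.94, 0.30), (8.71, 0.30), (7.60, 0.40)],
    "Guanosine": [(7.98, 0.60), (5.84, 0.40)],
    "UDP-galactose": [(5.64, 0.50), (5.98, 0.50)],
    "Formate": [(8.46, 1.00)],
}

# Unassigned resonances: broadish humps in gaps between the assigned
# multiplets.  They stand in for the many real signals the assignment does
# not cover, and their group level is used to balance total spectral area.
_UNASSIGNED_POSITIONS: list[tuple[float, float, float]] = [
    # (center ppm, weight, hwhm)
    (0.68, 0.06, 0.006),
    (0.86, 0.05, 0.006),
    (1.18, 0.08, 0.006),
    (1.58, 0.07, 0.006),
    (2.02, 0.05, 0.006),
    (2.25, 0.05, 0.006),
    (2.88, 0.05, 0.006),
    (3.12, 0.06, 0.006),
    (3.34, 0.07, 0.006),
    (3.52, 0.06, 0.006),
    (4.05, 0.07, 0.006),
    (4.32, 0.06, 0.006),
    (4.44, 0.05, 0.006),
    (5.10, 0.04, 0.006),
    (6.30, 0.04, 0.006),
    (6.72, 0.04, 0.006),
    (7.70, 0.05, 0.006),
    (8.60, 0.05, 0.006),
]

# Reference-group mean abundances (arbitrary integral units): dominant tissue
# metabolites (glucose, lactate, taurine, creatine, glutamate) are given
# realistically larger pools than aromatic trace compounds.
_REFERENCE_ABUNDANCES: dict[str, float] = {
    "Isoleucine": 0.8, "Leucine": 1.2, "Valine": 0.8, "Lactate": 6.0,
    "Alanine": 1.5, "Lysine": 1.5, "Acetate": 1.0, "Glutamate": 3.0,
    "Glutamine": 2.0, "Methionine": 0.6, "Succinate": 0.8, "Aspartate": 1.0,
    "Glutathione": 1.5, "Dimethylamine": 0.3, "Creatine": 2.5, "PCr": 1.5,
    "Choline": 1.0, "OPC": 1.0, "Betaine": 2.0, "Taurine": 4.0,
    "Glucose": 8.0, "Maltose": 1.5, "Glycine": 2.0, "Inosine": 0.8,
    "Uracil": 0.3, "Uridine": 0.5, "Fumarate": 0.1, "Tyrosine": 0.5,
    "Histidine": 0.4, "Phenylalanine": 0.5, "Hypoxanthine": 0.5,
    "Nicotinurate": 0.3, "Guanosine": 0.3, "UDP-galactose": 0.5,
    "Formate": 0.2,
}

# Published intestine fold changes per group, each column relative to the
# column's comparison group: model vs control, CNC vs model, JHC vs model.
_INTESTINE_FC: dict[str, tuple[float, float, float]] = {
    "Isoleucine": (1.80, 0.61, 0.83),
    "Leucine": (1.92, 0.58, 0.73),
    "Valine": (1.58, 0.63, 0.87),
    "Lactate": (0.84, 1.23, 0.93),
    "Alanine": (1.07, 1.00, 0.92),
    "Lysine": (1.63, 0.70, 0.75),
    "Acetate": (1.80, 0.70, 0.75),
    "Glutamate": (1.36, 0.66, 1.19),
    "Glutamine": (1.13, 0.63, 1.20),
    "Methionine": (1.67, 1.20, 0.97),
    "Succinate": (2.20, 0.34, 0.67),
    "Aspartate": (1.19, 0.81, 0.96),
    "Glutathione": (0.52, 1.38, 1.53),
    "Dimethylamine": (0.93, 1.23, 0.98),
    "Creatine": (0.96, 1.01, 1.08),
    "PCr": (0.96, 1.01, 1.08),
    "Choline": (0.93, 0.99, 1.10),
    "OPC": (0.81, 1.30, 1.03),
    "Betaine": (0.69, 1.10, 0.98),
    "Taurine": (0.87, 1.08, 1.10),
    "Glucose": (1.29, 0.80, 0.97),
    "Maltose": (1.89, 0.57, 0.90),
    "Glycine": (1.30, 1.10, 1.09),
    "Inosine": (1.05, 0.92, 0.85),
    "Uracil": (1.05, 1.02, 0.99),
    "Uridine": (1.20, 0.82, 0.92),
    "Fumarate": (0.96, 0.97, 0.92),
    "Tyrosine": (1.40, 0.83, 0.75),
    "Histidine": (0.96, 0.94, 0.96),
    "Phenylalanine": (1.17, 0.83, 0.71),
    "Hypoxanthine": (1.42, 1.00, 1.05),
    "Nicotinurate": (0.62, 0.96, 0.91),
    "Guanosine": (0.90, 0.95, 0.92),
    "UDP-galactose": (0.95, 0.98, 0.89),
    "Formate": (0.68, 1.26, 1.14),
}


def make_default_library() -> MetaboliteLibrary:
    """The 35-metabolite intestine library with reference resonance positions."""
    return MetaboliteLibrary(entries={k: _mk(v) for k, v in _INTESTINE_LIBRARY.items()})


def default_reference_abundances() -> dict[str, float]:
    return dict(_REFERENCE_ABUNDANCES)


def intestine_effect_table() -> pd.DataFrame:
    """Per-group true fold changes *relative to control* for the intestine study.

    The treatment columns are published relative to the model group, so the
    control-relative values are products (e.g. CNC = model_fc * cnc_vs_model).
    """
    rows = {}
    for name, (f_model, f_cnc, f_jhc) in _INTESTINE_FC.items():
        rows[name] = {
            "control": 1.0,
            "model": f_model,
            "CNC": f_model * f_cnc,
            "JHC": f_model * f_jhc,
        }
    return pd.DataFrame(rows).T[["control", "model", "CNC", "JHC"]]


@dataclass
class StudyDesign:
    """A multi-group study: sample counts, true effects, and noise structure.

    Fold changes are on the concentration scale, relative to ``reference``
    (whose column must be all ones).  ``noise_level`` and
    ``baseline_amplitude`` are relative to the median noiseless peak height
    of the reference mixture; ``shift_jitter`` is the s.d. (ppm) of the
    per-sample, per-metabolite resonance displacement; ``concentration_cv``
    is the log-normal coefficient of variation of concentrations around
    their group means.
    """

    groups: list[tuple[str, int]]
    effects: pd.DataFrame  # metabolite x group fold changes vs reference
    reference: str = "control"
    tissue: str = "intestine"
    noise_level: float = 0.02
    shift_jitter: float = 0.002
    baseline_amplitude: float = 0.01
    concentration_cv: float = 0.20
    dilution_cv: float = 0.10
    unassigned_ratio: float = 0.5  # unassigned pool as fraction of assigned total
    balance_totals: bool = True
    reference_abundances: dict[str, float] = field(
        default_factory=default_reference_abundances
    )
    seed: int = 0

    def __post_init__(self) -> None:
        names = [g for g, _ in self.groups]
        if self.reference not in names:
            raise ValueError(f"reference group {self.reference!r} not in groups")
        for g, n in self.groups:
            if n < 2:
                raise ValueError(f"group {g!r} needs >= 2 samples, got {n}")
        missing = [g for g in names if g not in self.effects.columns]
        if missing:
            raise ValueError(f"effect table lacks columns for groups: {missing}")
        if not np.allclose(self.effects[self.reference], 1.0):
            raise ValueError("reference group must have all fold changes = 1")
        if (self.effects[names] <= 0).any().any():
            raise ValueError("fold changes must be > 0")

    def group_names(self) -> list[str]:
        return [g for g, _ in self.groups]


def intestine_design(
    n_per_group: dict[str, int] | None = None, seed: int = 0, **overrides
) -> StudyDesign:
    """The default intestine study: groups 7/16/12/9 and published effects."""
    counts = {"control": 7, "model": 16, "JHC": 12, "CNC": 9}
    if n_per_group:
        counts.update(n_per_group)
    effects = intestine_effect_table()
    groups = [(g, counts[g]) for g in ["control", "model", "JHC", "CNC"] if counts[g] > 0]
    return StudyDesign(groups=groups, effects=effects, seed=seed, **overrides)


def lorentzian(x: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    """Unit-area Lorentzian line shape."""
    return (hwhm / np.pi) / ((x - center) ** 2 + hwhm**2)


def default_axis(
    ppm_range: tuple[float, float] = DEFAULT_PPM_RANGE, n_points: int = DEFAULT_N_POINTS
) -> np.ndarray:
    """Descending ppm grid (desk-scale stand-in for a 32K acquisition)."""
    lo, hi = ppm_range
    return np.linspace(hi, lo, n_points)


def _mixture(
    concentrations: dict[str, float],
    multiplets: dict[str, list[Multiplet]],
    axis: np.ndarray,
    jitter: dict[str, float] | None = None,
) -> np.ndarray:
    y = np.zeros_like(axis)
    for name, conc in concentrations.items():
        if conc == 0.0:
            continue
        shift = 0.0 if jitter is None else jitter.get(name, 0.0)
        for m in multiplets[name]:
            y += conc * m.weight * lorentzian(axis, m.center + shift, m.hwhm)
    return y


def simulate_spectrum(
    concentrations: dict[str, float],
    library: MetaboliteLibrary,
    axis: np.ndarray | None = None,
    noise_sd: float = 0.0,
    jitter_sd: float = 0.0,
    baseline_amplitude: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate one spectrum: Lorentzian mixture + baseline + Gaussian noise.

    Intensities are clipped at zero.  Jitter displaces each metabolite's
    multiplets coherently (pH-type drift).  Returns the intensity vector on
    ``axis`` (descending ppm).
    """
    if axis is None:
        axis = default_axis()
    axis = np.asarray(axis, dtype=float)
    if axis.size == 0:
        raise ValueError("empty ppm axis")
    unknown = [n for n in concentrations if n not in library]
    if unknown:
        raise KeyError(f"unknown metabolites: {unknown}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    jitter = None
    if jitter_sd > 0:
        jitter = {n: rng.normal(0.0, jitter_sd) for n in concentrations}
    y = _mixture(concentrations, library.entries, axis, jitter)

    if baseline_amplitude > 0:
        span = axis.max() - axis.min()
        phase = rng.uniform(0, 2 * np.pi)
        y += baseline_amplitude * (
            0.6 + 0.4 * np.sin(2 * np.pi * (axis - axis.min()) / max(span, 1e-9) + phase)
        )
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=axis.size)
    return np.clip(y, 0.0, None)


def _median_peak_height(
    abundances: dict[str, float], library: MetaboliteLibrary
) -> float:
    heights = [
        abundances[name] * m.weight / (np.pi * m.hwhm)
        for name, mult in library.entries.items()
        for m in mult
        if abundances.get(name, 0.0) > 0
    ]
    return float(np.median(heights)) if heights else 0.0


def _lognormal_around_mean(rng, mean, cv, size=None):
    """Draws with E[X] = mean and coefficient of variation cv."""
    if cv <= 0:
        return np.broadcast_to(np.asarray(mean, dtype=float), np.shape(mean) if size is None else size).copy()
    sigma = np.sqrt(np.log1p(cv**2))
    z = rng.normal(0.0, 1.0, size=size if size is not None else np.shape(mean))
    return np.asarray(mean, dtype=float) * np.exp(sigma * z - sigma**2 / 2.0)


def simulate_study(
    design: StudyDesign,
    library: MetaboliteLibrary | None = None,
    axis: np.ndarray | None = None,
) -> tuple[SpectraSet, pd.DataFrame]:
    """Simulate a full study; returns spectra and the true concentration table.

    Per sample, metabolite concentrations are drawn log-normally around
    (reference abundance x group fold change); an unassigned-signal pool
    balances the expected total area across groups (when
    ``design.balance_totals``); a per-sample dilution factor multiplies the
    whole spectrum (removed downstream by constant-sum normalization).
    Identical seeds give bit-identical output.
    """
    if library is None:
        library = make_default_library()
    if axis is None:
        axis = default_axis()
    missing = [m for m in design.effects.index if m not in library]
    if missing:
        raise KeyError(f"effect table references metabolites absent from library: {missing}")

    abundances = {
        name: design.reference_abundances.get(name, 1.0) for name in design.effects.index
    }
    assigned_total = sum(abundances.values())
    pool_base = design.unassigned_ratio * assigned_total

    # expected assigned totals per group, used for the closure pool
    group_totals = {
        g: float(sum(abundances[m] * design.effects.loc[m, g] for m in design.effects.index))
        for g in design.group_names()
    }

    unassigned_entries = {
        f"unassigned_{i}": [Multiplet(center=c, weight=1.0, hwhm=h)]
        for i, (c, w, h) in enumerate(_UNASSIGNED_POSITIONS)
    }
    unassigned_weights = np.array([w for _, w, _ in _UNASSIGNED_POSITIONS])
    unassigned_weights = unassigned_weights / unassigned_weights.sum()
    all_multiplets = dict(library.entries)
    all_multiplets.update(unassigned_entries)

    noise_sd = design.noise_level * _median_peak_height(abundances, library)
    baseline_amp = design.baseline_amplitude * _median_peak_height(abundances, library)

    # separate streams: concentrations (ground truth) must not depend on the
    # grid size consumed by the noise draws
    rng = np.random.default_rng([design.seed, 1])
    rng_noise = np.random.default_rng([design.seed, 2])
    rows, meta_rows, truth_rows, ids = [], [], [], []
    metabolites = list(design.effects.index)
    for group, n in design.groups:
        pool_mean = pool_base
        if design.balance_totals:
            pool_mean = pool_base + (group_totals[design.reference] - group_totals[group])
            if pool_mean <= 0:
                raise ValueError(
                    f"unassigned pool for group {group!r} is non-positive; "
                    "increase unassigned_ratio"
                )
        for k in range(n):
            sid = f"{group}_{k + 1:02d}"
            means = np.array(
                [abundances[m] * design.effects.loc[m, group] for m in metabolites]
            )
            conc = _lognormal_around_mean(rng, means, design.concentration_cv)
            pool_conc = _lognormal_around_mean(
                rng, pool_mean * unassigned_weights, design.concentration_cv
            )
            dilution = float(
                _lognormal_around_mean(rng, np.array(1.0), design.dilution_cv)
            )
            sample_conc = {m: dilution * c for m, c in zip(metabolites, conc)}
            sample_conc.update(
                {
                    f"unassigned_{i}": dilution * c
                    for i, c in enumerate(pool_conc)
                }
            )
            jitter = None
            if design.shift_jitter > 0:
                jitter = {
                    m: rng_noise.normal(0.0, design.shift_jitter) for m in sample_conc
                }
            y = _mixture(sample_conc, all_multiplets, axis, jitter)
            if baseline_amp > 0:
                phase = rng_noise.uniform(0, 2 * np.pi)
                span = axis.max() - axis.min()
                y = y + dilution * baseline_amp * (
                    0.6 + 0.4 * np.sin(2 * np.pi * (axis - axis.min()) / span + phase)
                )
            if noise_sd > 0:
                y = y + rng_noise.normal(0.0, noise_sd, size=axis.size)
            rows.append(np.clip(y, 0.0, None))
            ids.append(sid)
            meta_rows.append({"group": group, "tissue": design.tissue})
            truth_rows.append(dict(zip(metabolites, conc)))  # pre-dilution truth

    metadata = pd.DataFrame(meta_rows, index=ids)
    truth = pd.DataFrame(truth_rows, index=ids)[metabolites]
    spectra = SpectraSet(ppm=axis.copy(), intensities=np.vstack(rows), metadata=metadata)
    return spectra, truth
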