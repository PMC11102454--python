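"""Synthetic study-design data generators.

These emulate the statistical structure of the animal study the analysis
assumes: 5 dose groups (0.1–3.5 mg/animal), 3 mice per group per time
point, blood sampling from 2 min to 48 h, endpoint biodistribution at
3/6/24/48 h expressed relative to the liver, one-phase-decay-like blood
kinetics, and multiplicative lognormal measurement noise with ~10% CV.
Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DoseSchedule, simulate
from .parameters import PBPKParameters
from .physiology import PhysiologyTable

#: non-liver organs with measured endpoint biodistribution
MEASURED_ORGANS = ("lung", "spleen", "kidney", "heart", "bone")


@dataclass(frozen=True)
class StudyDesign:
    """The animal-study layout the generators emulate."""

    doses_mg: tuple[float, ...] = (0.1, 0.5, 2.0, 2.5, 3.5)
    n_animals: int = 3
    blood_times: tuple[float, ...] = (0.033, 0.167, 0.25, 0.5, 1, 2, 4, 8, 10, 24, 48)
    biodist_times: tuple[float, ...] = (3.0, 6.0, 24.0, 48.0)
    biodist_dose_mg: float = 0.5
    organs: tuple[str, ...] = MEASURED_ORGANS
    noise_sd: float = 0.10  # lognormal sigma (≈ CV of multiplicative noise)
    seed: int | None = None

    def __post_init__(self) -> None:
        for times in (self.blood_times, self.biodist_times):
            if np.any(np.diff(times) <= 0):
                raise ValueError("sampling times must be strictly increasing")
        if self.n_animals < 1:
            raise ValueError("need at least one animal per group")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")


@dataclass
class BloodPKDataset:
    """Per-animal blood concentrations: rows (dose, animal, time, concentration)."""

    rows: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        g = self.rows.groupby(["dose", "time"])["concentration"]
        out = g.agg(mean="mean", sd="std", n="count").reset_index()
        out["sd"] = out["sd"].fillna(0.0)
        out["sem"] = out["sd"] / np.sqrt(out["n"])
        return out

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BloodPKDataset":
        return cls(pd.read_csv(path))


@dataclass
class BiodistributionDataset:
    """Organ values relative to liver: rows (organ, time, value, sem, n).

    The liver reference row is identically 1 (sem 0) at every time point.
    """

    rows: pd.DataFrame
    raw: pd.DataFrame | None = field(default=None, repr=False)  # per-animal ratios

    def __post_init__(self) -> None:
        liver = self.rows[self.rows.organ == "liver"]
        times = set(self.rows.time.unique())
        if set(liver.time) != times or not np.allclose(liver.value, 1.0):
            raise ValueError("liver reference row must be 1 at every time point")
        if (self.rows.value < 0).any():
            raise ValueError("relative values must be nonnegative")

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BiodistributionDataset":
        return cls(pd.read_csv(path))


def _noise(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    if sigma == 0:
        return np.ones(size)
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def generate_from_model(
    truth_params: PBPKParameters,
    phys: PhysiologyTable,
    design: StudyDesign,
    seed: int | None = None,
    solver_opts: dict | None = None,
) -> tuple[BloodPKDataset, BiodistributionDataset]:
    """Simulate the full study from a known ground-truth parameter set.

    Blood observations are per-animal model values times multiplicative
    lognormal noise; biodistribution observations are per-animal noisy
    organ/liver tissue-concentration ratios at the endpoint dose.
    """
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    t_grid = np.unique(
        np.concatenate([[0.0], design.blood_times, design.biodist_times])
    )

    blood_rows = []
    biodist_raw = []
    for dose_mg in design.doses_mg:
        sim = simulate(
            truth_params, phys, DoseSchedule.from_mg(dose_mg), t_grid, solver_opts
        )
        model_c = np.interp(design.blood_times, sim.t, sim.blood_concentration)
        for animal in range(design.n_animals):
            eps = _noise(rng, design.noise_sd, len(design.blood_times))
            for t, c in zip(design.blood_times, model_c * eps):
                blood_rows.append((dose_mg, f"d{dose_mg}-a{animal + 1}", t, c))
        if np.isclose(dose_mg, design.biodist_dose_mg):
            liver_c = np.interp(design.biodist_times, sim.t, sim.tissue_concentration("liver"))
            for organ in design.organs:
                organ_c = np.interp(
                    design.biodist_times, sim.t, sim.tissue_concentration(organ)
                )
                for j, t in enumerate(design.biodist_times):
                    for animal in range(design.n_animals):
                        num, den = _noise(rng, design.noise_sd, 2)
                        biodist_raw.append(
                            (organ, t, organ_c[j] * num / (liver_c[j] * den), animal + 1)
                        )

    blood = BloodPKDataset(
        pd.DataFrame(blood_rows, columns=["dose", "animal", "time", "concentration"])
    )
    raw = pd.DataFrame(biodist_raw, columns=["organ", "time", "value", "animal"])
    g = raw.groupby(["organ", "time"])["value"]
    summary = g.agg(value="mean", sd="std", n="count").reset_index()
    summary["sd"] = summary["sd"].fillna(0.0)
    summary["sem"] = summary["sd"] / np.sqrt(summary["n"])
    liver_rows = pd.DataFrame(
        {
            "organ": "liver",
            "time": list(design.biodist_times),
            "value": 1.0,
            "sd": 0.0,
            "n": design.n_animals,
            "sem": 0.0,
        }
    )
    summary = pd.concat([summary, liver_rows], ignore_index=True)
    return blood, BiodistributionDataset(summary, raw=raw)


def generate_decay_dataset(
    C0: float,
    t_half: float,
    design: StudyDesign,
    sigma: float | None = None,
    seed: int | None = None,
    dose_label: float = 0.0,
) -> BloodPKDataset:
    """Per-animal samples of a one-phase decay C0·exp(-ln2·t/t_half) with
    multiplicative lognormal noise — the fixture for the half-life
    estimator."""
    if C0 <= 0 or t_half <= 0:
        raise ValueError("C0 and t_half must be positive")
    sigma = design.noise_sd if sigma is None else sigma
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    times = np.asarray(design.blood_times, dtype=float)
    truth = C0 * np.exp(-np.log(2.0) * times / t_half)
    rows = []
    for animal in range(design.n_animals):
        eps = _noise(rng, sigma, len(times))
        for t, c in zip(times, truth * eps):
            rows.append((dose_label, f"a{animal + 1}", t, c))
    return BloodPKDataset(
        pd.DataFrame(rows, columns=["dose", "animal", "time", "concentration"])
    )


#: serial dilution standards, μg/mL (doubling dilutions from 250 plus blank)
STANDARD_CONCENTRATIONS = (0.0, 15.625, 31.25, 62.5, 125.0, 250.0)


def generate_plate(
    design: StudyDesign,
    curve_truth: tuple[float, float],
    seed: int | None = None,
    decay_truth: tuple[float, float] = (250.0, 24.0),
    image_shape: tuple[int, int] = (16, 16),
    n_images: int = 9,
    noise_frac: float = 0.01,
    n_standard_replicates: int = 2,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Synthetic 384-well plate for the quantification chain.

    Standard wells follow ``intensity_sum = slope·conc + intercept`` plus
    Gaussian noise (sd = ``noise_frac`` of the full-scale signal); sample
    wells hold a noiseless one-phase-decay blood series imaged the same
    way.  Returns ``(well images, plate layout)`` where each well is an
    ``(n_images, h, w)`` stack whose per-frame pixel sums realize the
    target intensity.
    """
    slope, intercept = curve_truth
    if slope <= 0:
        raise ValueError("standard-curve slope must be positive")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    npix = image_shape[0] * image_shape[1]
    noise_sd = noise_frac * slope * max(STANDARD_CONCENTRATIONS)

    def well_stack(conc: float) -> np.ndarray:
        target = slope * conc + intercept + rng.normal(0.0, noise_sd, n_images)
        return (target / npix)[:, None, None] * np.ones((1, *image_shape))

    wells: dict[str, np.ndarray] = {}
    layout = []
    for i, conc in enumerate(STANDARD_CONCENTRATIONS):
        for r in range(n_standard_replicates):
            wid = f"STD{i + 1}{'abcdefgh'[r]}"
            wells[wid] = well_stack(conc)
            layout.append((wid, "standard", conc, "", np.nan))
    C0, t_half = decay_truth
    times = np.asarray(design.blood_times, dtype=float)
    for animal in range(design.n_animals):
        for t in times:
            conc = C0 * np.exp(-np.log(2.0) * t / t_half)
            wid = f"S-a{animal + 1}-t{t:g}"
            wells[wid] = well_stack(conc)
            layout.append((wid, "sample", np.nan, f"a{animal + 1}", t))
    layout_df = pd.DataFrame(
        layout, columns=["well", "role", "concentration", "animal", "time"]
    )
    return wells, layout_df


def write_plate(wells: dict[str, np.ndarray], layout: pd.DataFrame, outdir) -> None:
    """Write each well as a multi-frame TIFF plus the layout CSV."""
    import pathlib

    import tifffile

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for wid, stack in wells.items():
        tifffile.imwrite(outdir / f"{wid}.tif", stack.astype(np.float32))
    layout.to_csv(outdir / "layout.csv", index=False)


def read_plate(indir) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    import pathlib

    import tifffile

    indir = pathlib.Path(indir)
    layout = pd.read_csv(indir / "layout.csv", keep_default_na=True)
    wells = {
        wid: tifffile.imread(indir / f"{wid}.tif") for wid in layout.well
    }
    return wells, layout
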