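"""Per-organ kinetic parameters of the nanoparticle PBPK model.

Each organ carries a permeability–flow product ``PA`` (mL/h), a
tissue:plasma distribution coefficient ``P``, Hill phagocytosis-uptake
constants (``K_max`` 1/h, ``K_50`` h, ``n_H``), a phagocytic release rate
``K_rel`` (1/h) and an elimination clearance ``K_elim`` (mL/h) that is
nonzero only for the liver (biliary, ``K_bile``) and the kidney (urinary,
``K_urine``).  For the PEGylated polymer reference configuration
``K_urine = 0``, so bile is the sole route of elimination.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import pandas as pd

from .physiology import ORGANS, PHAGOCYTIC_ORGANS

_FIELDS = ("PA", "P", "K_max", "K_50", "n_H", "K_rel", "K_elim")
_UNITS = {
    "PA": "mL/h",
    "P": "dimensionless",
    "K_max": "1/h",
    "K_50": "h",
    "n_H": "dimensionless",
    "K_rel": "1/h",
    "K_elim": "mL/h",
}


@dataclass(frozen=True)
class OrganParameters:
    PA: float = 0.0
    P: float = 1.0
    K_max: float = 0.0
    K_50: float = 0.0
    n_H: float = 1.0
    K_rel: float = 0.0
    K_elim: float = 0.0

    def __post_init__(self) -> None:
        for name in _FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.PA > 0 and self.P == 0:
            raise ValueError("P must be positive when PA is nonzero (division by P)")


@dataclass(frozen=True)
class PBPKParameters:
    """Kinetic constants for every organ of a :class:`PhysiologyTable`."""

    per_organ: dict[str, OrganParameters]

    def __post_init__(self) -> None:
        for organ, p in self.per_organ.items():
            if organ not in PHAGOCYTIC_ORGANS and p.K_max != 0:
                raise ValueError(
                    f"{organ!r} has no phagocytic subcompartment; K_max must be 0"
                )
            if organ not in ("liver", "kidney") and p.K_elim != 0:
                raise ValueError(f"K_elim must be 0 for {organ!r} (no excretory route)")

    def __getitem__(self, organ: str) -> OrganParameters:
        return self.per_organ[organ]

    @property
    def K_bile(self) -> float:
        return self.per_organ["liver"].K_elim

    @property
    def K_urine(self) -> float:
        return self.per_organ["kidney"].K_elim

    # ------------------------------------------------- flat-name access

    def flat_names(self, skip_zero: bool = False) -> list[str]:
        """``organ.field`` names, e.g. ``liver.K_max``; ``liver.K_elim`` is
        the biliary clearance K_bile."""
        names = []
        for organ, p in self.per_organ.items():
            for f in _FIELDS:
                if skip_zero and getattr(p, f) == 0:
                    continue
                names.append(f"{organ}.{f}")
        return names

    def get_value(self, name: str) -> float:
        organ, field = name.split(".")
        return getattr(self.per_organ[organ], field)

    def with_value(self, name: str, value: float) -> "PBPKParameters":
        organ, field = name.split(".")
        new = dict(self.per_organ)
        new[organ] = replace(new[organ], **{field: value})
        return PBPKParameters(new)

    def with_values(self, values: dict[str, float]) -> "PBPKParameters":
        out = self
        for name, value in values.items():
            out = out.with_value(name, value)
        return out

    # ---------------------------------------------------------------- I/O

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PBPKParameters":
        per_organ = {}
        for organ, grp in df.groupby("organ", sort=False):
            vals = dict(zip(grp.parameter, grp.value.astype(float)))
            per_organ[organ] = OrganParameters(**{f: vals.get(f, 0.0) for f in _FIELDS})
        ordered = {o: per_organ[o] for o in ORGANS if o in per_organ}
        ordered.update({o: p for o, p in per_organ.items() if o not in ordered})
        return cls(ordered)

    @classmethod
    def from_csv(cls, path) -> "PBPKParameters":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def reference(cls) -> "PBPKParameters":
        """Reference PEGylated-polymer parameterization shipped with the
        package (K_urine = 0; near-immediate liver/spleen phagocytosis
        onset; 125 h kidney half-maximum time)."""
        ref = importlib.resources.files("nanopbpk.data") / "reference_parameters.csv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_csv(path)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (organ, f, getattr(p, f), _UNITS[f])
            for organ, p in self.per_organ.items()
            for f in _FIELDS
        ]
        return pd.DataFrame(rows, columns=["organ", "parameter", "value", "units"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
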