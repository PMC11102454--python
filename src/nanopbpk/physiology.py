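"""Whole-body mouse physiology: organ blood flows and compartment volumes.

The circulatory topology is the standard whole-body PBPK layout: the venous
pool feeds the lung (which receives the full cardiac output, in series), the
lung feeds the arterial pool, and all remaining organs sit in parallel
between the arterial and venous pools.  Splenic venous outflow is routed
through the liver (portal convention), so the liver's total perfusion is its
arterial inflow plus the splenic flow.

Units are fixed package-wide: volumes in mL, flows in mL/h.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

#: canonical organ ordering used throughout the package
ORGANS = ("lung", "liver", "spleen", "kidney", "heart", "bone", "brain", "other")

#: organs with a phagocytic (mononuclear-phagocyte) subcompartment
PHAGOCYTIC_ORGANS = frozenset({"lung", "liver", "spleen", "kidney"})

#: organs whose venous outflow drains through the liver (portal convention)
PORTAL_ORGANS = ("spleen",)

_REL_TOL = 1e-9


@dataclass(frozen=True)
class PhysiologyTable:
    """Organ blood flows ``Q`` (mL/h) and subcompartment volumes (mL).

    ``Q['lung']`` equals the cardiac output because the lung is perfused in
    series; the flows of all other organs sum to the cardiac output.
    """

    organs: tuple[str, ...]
    Q: dict[str, float]
    V_vasc: dict[str, float]
    V_extra: dict[str, float]
    V_art: float
    V_ven: float
    cardiac_output: float = field(default=0.0)

    def __post_init__(self) -> None:
        co = self.cardiac_output or self.Q.get("lung", 0.0)
        object.__setattr__(self, "cardiac_output", co)
        for organ in self.organs:
            for table, label in ((self.Q, "Q"), (self.V_vasc, "V_vasc"), (self.V_extra, "V_extra")):
                if organ not in table:
                    raise ValueError(f"missing {label} entry for organ {organ!r}")
                if table[organ] <= 0:
                    raise ValueError(f"{label}[{organ!r}] must be strictly positive")
        if self.V_art <= 0 or self.V_ven <= 0:
            raise ValueError("arterial and venous blood volumes must be strictly positive")
        if abs(self.Q["lung"] - co) > _REL_TOL * co:
            raise ValueError("lung blood flow must equal the cardiac output (series perfusion)")
        systemic = sum(self.Q[o] for o in self.organs if o != "lung")
        if abs(systemic - co) > _REL_TOL * co:
            raise ValueError(
                f"systemic organ flows sum to {systemic} mL/h but cardiac output is {co} mL/h"
            )

    @property
    def blood_volume(self) -> float:
        """Pooled arterial + venous blood volume (mL), the denominator of
        reported blood concentrations."""
        return self.V_art + self.V_ven

    def perfusion(self, organ: str) -> float:
        """Total vascular inflow of *organ* (mL/h), including portal flow."""
        q = self.Q[organ]
        if organ == "liver":
            q += sum(self.Q[o] for o in PORTAL_ORGANS)
        return q

    # ---------------------------------------------------------------- I/O

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhysiologyTable":
        pivot: dict[tuple[str, str], float] = {
            (r.organ, r.parameter): float(r.value) for r in df.itertuples()
        }
        organs = tuple(o for o in ORGANS if (o, "Q") in pivot)
        extra = [o for o in df.organ.unique() if o not in organs and o != "blood"]
        organs += tuple(extra)
        return cls(
            organs=organs,
            Q={o: pivot[(o, "Q")] for o in organs},
            V_vasc={o: pivot[(o, "V_vasc")] for o in organs},
            V_extra={o: pivot[(o, "V_extra")] for o in organs},
            V_art=pivot[("blood", "V_art")],
            V_ven=pivot[("blood", "V_ven")],
            cardiac_output=pivot.get(("blood", "cardiac_output"), 0.0),
        )

    @classmethod
    def from_csv(cls, path) -> "PhysiologyTable":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def default(cls) -> "PhysiologyTable":
        """Literature-typical 25 g mouse physiology shipped with the package."""
        ref = importlib.resources.files("nanopbpk.data") / "mouse_physiology.csv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_csv(path)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for o in self.organs:
            rows.append((o, "Q", self.Q[o], "mL/h"))
            rows.append((o, "V_vasc", self.V_vasc[o], "mL"))
            rows.append((o, "V_extra", self.V_extra[o], "mL"))
        rows.append(("blood", "V_art", self.V_art, "mL"))
        rows.append(("blood", "V_ven", self.V_ven, "mL"))
        rows.append(("blood", "cardiac_output", self.cardiac_output, "mL/h"))
        return pd.DataFrame(rows, columns=["organ", "parameter", "value", "units"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
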