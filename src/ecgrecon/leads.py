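"""Standard 12-lead geometry: canonical ordering and dipole-projection algebra.

The canonical lead order used everywhere in this package is
I, II, III, aVR, aVL, aVF, V1..V6 (indices 0-11).

Surface leads are modelled as linear projections of a 3-D cardiac dipole
(vectorcardiographic view).  The limb leads live in the frontal plane at their
classical hexaxial angles (I at 0 deg, II at +60 deg); the augmented leads
follow exactly from Goldberger's definitions, and the precordial leads are
fixed unit vectors spanning the horizontal plane.  Dipole axes are
x = leftward, y = inferior, z = anterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CANONICAL_LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

LEAD_INDEX: dict[str, int] = {name: i for i, name in enumerate(CANONICAL_LEADS)}

#: Frontal-plane hexaxial angles (degrees) of the two independent limb leads.
LIMB_ANGLES_DEG = {"I": 0.0, "II": 60.0}

#: Horizontal-plane angles (degrees from the x axis toward anterior z) of the
#: precordial unit vectors.  V1 points right-anterior, V6 leftward.
PRECORDIAL_ANGLES_DEG = {
    "V1": 120.0, "V2": 95.0, "V3": 70.0, "V4": 45.0, "V5": 20.0, "V6": 0.0,
}


def goldberger_rows(row_i: np.ndarray, row_ii: np.ndarray) -> dict[str, np.ndarray]:
    """Rows of III, aVR, aVL, aVF from the rows of I and II (exact algebra)."""
    return {
        "III": row_ii - row_i,
        "aVR": -(row_i + row_ii) / 2.0,
        "aVL": row_i - row_ii / 2.0,
        "aVF": row_ii - row_i / 2.0,
    }


@dataclass(frozen=True)
class LeadMatrix:
    """12x3 projection from dipole space to lead space (dimensionless gain).

    Rows follow :data:`CANONICAL_LEADS`.  The dependent limb rows are forced
    through the Einthoven/Goldberger identities at construction, so
    III = II - I and aVR + aVL + aVF = 0 hold exactly for any input.
    """

    matrix: np.ndarray = field()

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (12, 3):
            raise ValueError(f"lead matrix must be 12x3, got {m.shape}")
        object.__setattr__(self, "matrix", m)
        dep = goldberger_rows(m[0], m[1])
        for name, row in dep.items():
            if not np.array_equal(m[LEAD_INDEX[name]], row):
                raise ValueError(f"row {name} violates limb-lead algebra")
        sub = m[[LEAD_INDEX["II"], LEAD_INDEX["V1"], LEAD_INDEX["V5"]]]
        if np.linalg.matrix_rank(sub) != 3:
            raise ValueError("rows II, V1, V5 must span dipole space")

    @classmethod
    def from_independent_rows(cls, row_i, row_ii, precordial: dict[str, np.ndarray]
                              ) -> "LeadMatrix":
        m = np.zeros((12, 3))
        m[LEAD_INDEX["I"]] = row_i
        m[LEAD_INDEX["II"]] = row_ii
        for name, row in goldberger_rows(np.asarray(row_i, float),
                                         np.asarray(row_ii, float)).items():
            m[LEAD_INDEX[name]] = row
        for name, row in precordial.items():
            m[LEAD_INDEX[name]] = row
        return cls(m)

    @classmethod
    def default(cls) -> "LeadMatrix":
        th_i = np.deg2rad(LIMB_ANGLES_DEG["I"])
        th_ii = np.deg2rad(LIMB_ANGLES_DEG["II"])
        row_i = np.array([np.cos(th_i), np.sin(th_i), 0.0])
        row_ii = np.array([np.cos(th_ii), np.sin(th_ii), 0.0])
        precordial = {}
        for name, deg in PRECORDIAL_ANGLES_DEG.items():
            phi = np.deg2rad(deg)
            precordial[name] = np.array([np.cos(phi), 0.0, np.sin(phi)])
        return cls.from_independent_rows(row_i, row_ii, precordial)

    def project(self, dipole: np.ndarray) -> np.ndarray:
        """Project a [3 x T] dipole trajectory to [12 x T] lead voltages."""
        dipole = np.asarray(dipole)
        if dipole.ndim != 2 or dipole.shape[0] != 3:
            raise ValueError(f"dipole must be [3 x T], got {dipole.shape}")
        return self.matrix @ dipole


def lead_indices(names) -> list[int]:
    """Canonical indices for a sequence of lead names (case preserved)."""
    try:
        return [LEAD_INDEX[n] for n in names]
    except KeyError as exc:
        raise ValueError(f"unknown lead name {exc.args[0]!r}") from exc
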