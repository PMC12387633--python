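"""Deterministic mass-spectrometric annotation arithmetic.

The numerical machinery behind lipid annotation from LC-HRMS2 data and
compound indexing from GC-MS data:

* monoisotopic masses of molecular formulas from a shipped isotope table;
* adduct m/z ([M+H]+, [M+Na]+, [M-H2O+H]+, ...) with explicit electron-mass
  handling;
* ppm mass errors;
* betaine-lipid (DGTA/DGTS) headgroup detection via the diagnostic fragment
  pair m/z 236.1498 (C10H22NO5+) and 144.1025 (C7H14NO2+);
* fatty-acyl chain identification by neutral loss of the chain as free acid
  (-RCOOH) or ketene (-R=C=O);
* Kovats (Van den Dool & Kratz) retention indices against an n-alkane
  ladder.

DGTA and DGTS are isobaric; nothing here attempts to distinguish them and
reports "DGTA/S" as one class.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

with resources.files("mbmetab.data").joinpath("isotope_masses.json").open() as _fh:
    _ISOTOPES = json.load(_fh)

ATOMIC_MASSES: dict[str, float] = dict(_ISOTOPES["masses"])
ELECTRON_MASS: float = float(_ISOTOPES["electron_mass"])

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map over the supported element set."""

    counts: tuple  # sorted tuple of (element, count)

    def __post_init__(self) -> None:
        for el, n in self.counts:
            if el not in ATOMIC_MASSES:
                raise ValueError(f"unsupported element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}")
        if sum(n for _, n in self.counts) == 0:
            raise ValueError("formula must contain at least one atom")

    @classmethod
    def from_counts(cls, **counts: int) -> "MolecularFormula":
        return cls(tuple(sorted((el, int(n)) for el, n in counts.items()
                                if n != 0)))

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        """Parse a Hill-style formula string such as ``"C10H22NO5"``."""
        pos, counts = 0, {}
        for m in _FORMULA_RE.finditer(text.strip()):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = m.end()
            el, n = m.group(1), int(m.group(2) or 1)
            counts[el] = counts.get(el, 0) + n
        if pos != len(text.strip()) or not counts:
            raise ValueError(f"cannot parse formula {text!r}")
        return cls.from_counts(**counts)

    def as_dict(self) -> dict:
        return dict(self.counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        d = self.as_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) + n
        return MolecularFormula.from_counts(**d)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        d = self.as_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) - n
            if d[el] < 0:
                raise ValueError(
                    f"removing {n} {el} exceeds the {self} composition")
        return MolecularFormula.from_counts(**d)

    def __str__(self) -> str:
        order = ["C", "H"] + sorted(el for el, _ in self.counts
                                    if el not in ("C", "H"))
        d = self.as_dict()
        return "".join(f"{el}{d[el] if d[el] != 1 else ''}"
                       for el in order if d.get(el))


def monoisotopic_mass(f: MolecularFormula | str, as_cation: bool = False,
                      electron_correction: bool = False) -> float:
    """Sum of most-abundant-isotope masses in Da.

    With ``as_cation`` and ``electron_correction`` both set, one electron
    mass is subtracted per positive charge.  The default leaves the
    electron out, matching the convention used for printed fragment-ion
    formulas at 4-decimal precision.
    """
    if isinstance(f, str):
        f = MolecularFormula.parse(f)
    m = sum(ATOMIC_MASSES[el] * n for el, n in f.counts)
    if as_cation and electron_correction:
        m -= ELECTRON_MASS
    return float(m)


@dataclass(frozen=True)
class AdductSpec:
    """Ionisation adduct: composition delta and charge.

    ``electron_correction`` (default on) subtracts/adds the electron mass
    per unit charge, the physically rigorous m/z convention.
    """

    name: str
    add: MolecularFormula | None = None
    sub: MolecularFormula | None = None
    charge: int = 1
    electron_correction: bool = True

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be nonzero")


_H = MolecularFormula.parse("H")
_H2O = MolecularFormula.parse("H2O")

COMMON_ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", add=_H),
    "[M+Na]+": AdductSpec("[M+Na]+", add=MolecularFormula.parse("Na")),
    "[M+K]+": AdductSpec("[M+K]+", add=MolecularFormula.parse("K")),
    "[M-H2O+H]+": AdductSpec("[M-H2O+H]+", add=_H, sub=_H2O),
    "[M+H2O+K]+": AdductSpec("[M+H2O+K]+",
                             add=MolecularFormula.parse("H2O") +
                             MolecularFormula.parse("K")),
    "[M-H]-": AdductSpec("[M-H]-", sub=_H, charge=-1),
}


def adduct_mz(f: MolecularFormula | str, adduct: AdductSpec | str) -> float:
    """m/z of the adduct ion: (mass(M) + mass(delta) -/+ z*m_e) / |z|."""
    if isinstance(f, str):
        f = MolecularFormula.parse(f)
    if isinstance(adduct, str):
        adduct = COMMON_ADDUCTS[adduct]
    composition = f
    if adduct.add is not None:
        composition = composition + adduct.add
    if adduct.sub is not None:
        composition = composition - adduct.sub  # raises on negative composition
    m = monoisotopic_mass(composition)
    if adduct.electron_correction:
        m -= adduct.charge * ELECTRON_MASS
    return m / abs(adduct.charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """(observed − theoretical) / theoretical × 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


# ---------------------------------------------------------------------------
# betaine-lipid diagnostics and acyl neutral losses
# ---------------------------------------------------------------------------

#: Diagnostic headgroup fragments of the isobaric DGTA/DGTS betaine lipids.
BETAINE_DIAGNOSTIC_FORMULAS = ("C10H22NO5", "C7H14NO2")
BETAINE_DIAGNOSTIC_MZ = tuple(monoisotopic_mass(f, as_cation=True)
                              for f in BETAINE_DIAGNOSTIC_FORMULAS)


def _within_ppm(observed: float, expected: float, tol_ppm: float) -> bool:
    return abs(ppm_error(observed, expected)) <= tol_ppm


def detect_betaine_headgroup(fragments, tol_ppm: float = 5.0,
                             require_both: bool = True) -> tuple[bool, dict]:
    """Detect the DGTA/S headgroup from an MS2 fragment list.

    Returns ``(detected, matches)`` where ``matches`` maps each diagnostic
    formula to the matched observed m/z (or ``None``).  By default both
    diagnostic ions must be present within ``tol_ppm``.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    fragments = np.asarray(list(fragments), float)
    matches: dict[str, float | None] = {}
    for formula, mz in zip(BETAINE_DIAGNOSTIC_FORMULAS, BETAINE_DIAGNOSTIC_MZ):
        hit = None
        for obs in fragments:
            if _within_ppm(obs, mz, tol_ppm):
                hit = float(obs)
                break
        matches[formula] = hit
    found = [m is not None for m in matches.values()]
    detected = all(found) if require_both else any(found)
    return detected, matches


@dataclass(frozen=True)
class AcylCandidate:
    """A fatty acyl chain C:D(;Ox) with its acid and ketene loss formulas."""

    carbons: int
    double_bonds: int = 0
    extra_oxygens: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError("acyl chain needs at least 2 carbons")
        if self.double_bonds < 0 or self.extra_oxygens < 0:
            raise ValueError("double bonds / extra oxygens must be >= 0")

    @property
    def name(self) -> str:
        base = f"{self.carbons}:{self.double_bonds}"
        return base + (f";O{self.extra_oxygens}" if self.extra_oxygens else "")

    @property
    def acid_formula(self) -> MolecularFormula:
        """Free fatty acid RCOOH: C_n H_{2n-2d} O_{2+x}."""
        return MolecularFormula.from_counts(
            C=self.carbons, H=2 * self.carbons - 2 * self.double_bonds,
            O=2 + self.extra_oxygens)

    @property
    def ketene_formula(self) -> MolecularFormula:
        """Ketene R=C=O: C_n H_{2n-2-2d} O_{1+x}."""
        return MolecularFormula.from_counts(
            C=self.carbons, H=2 * self.carbons - 2 - 2 * self.double_bonds,
            O=1 + self.extra_oxygens)


@dataclass(frozen=True)
class NeutralLossMatch:
    candidate: AcylCandidate
    loss_type: str          # "acid" | "ketene"
    loss_mass: float
    expected_mz: float
    observed_mz: float
    error_ppm: float


def match_neutral_losses(precursor_mz: float, fragments, candidates,
                         tol_ppm: float = 10.0) -> list[NeutralLossMatch]:
    """Assign acyl chains by acid/ketene neutral losses from the precursor.

    For every candidate chain the expected fragment m/z is the precursor
    minus the neutral mass of its acid and ketene forms; observed fragments
    within ``tol_ppm`` of an expectation yield a match.  Output order is
    (candidate, loss type) and therefore stable under permutation of the
    fragment list.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty acyl candidate list")
    fragments = sorted(float(x) for x in fragments)
    out: list[NeutralLossMatch] = []
    for cand in candidates:
        for loss_type, formula in (("acid", cand.acid_formula),
                                   ("ketene", cand.ketene_formula)):
            loss = monoisotopic_mass(formula)
            expected = precursor_mz - loss
            if expected <= 0:
                continue
            for obs in fragments:
                if _within_ppm(obs, expected, tol_ppm):
                    out.append(NeutralLossMatch(
                        cand, loss_type, loss, expected, obs,
                        ppm_error(obs, expected)))
    return out


# ---------------------------------------------------------------------------
# Kovats / Van den Dool & Kratz retention index
# ---------------------------------------------------------------------------

@dataclass
class AlkaneLadder:
    """n-alkane calibration ladder: (carbon number, retention time) rungs,
    strictly increasing in both."""

    rungs: list  # [(n, rt), ...]

    def __post_init__(self) -> None:
        if len(self.rungs) < 2:
            raise ValueError("ladder needs at least two rungs")
        ns = [n for n, _ in self.rungs]
        rts = [rt for _, rt in self.rungs]
        if sorted(ns) != ns or len(set(ns)) != len(ns):
            raise ValueError("carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("retention times must be strictly increasing")

    @property
    def span(self) -> tuple[float, float]:
        return self.rungs[0][1], self.rungs[-1][1]


def kovats_ri(rt: float, ladder: AlkaneLadder,
              extrapolate: bool = False) -> float:
    """Van den Dool & Kratz retention index, linear in retention time.

    ``RI = 100 * (n + (rt − rt_n) / (rt_{n+1} − rt_n))`` with (n, n+1) the
    bracketing alkanes.  ``rt`` outside the ladder span raises unless
    ``extrapolate`` is set, in which case the nearest segment is extended.
    """
    lo, hi = ladder.span
    if not extrapolate and not (lo <= rt <= hi):
        raise ValueError(
            f"rt {rt} outside alkane ladder span [{lo}, {hi}]; pass "
            f"extrapolate=True to extend the terminal segments")
    rungs = ladder.rungs
    # choose bracketing segment (clamped to terminal segments if outside)
    for k in range(len(rungs) - 1):
        if rungs[k][1] <= rt <= rungs[k + 1][1]:
            break
    else:
        k = 0 if rt < lo else len(rungs) - 2
    (n0, rt0), (n1, rt1) = rungs[k], rungs[k + 1]
    return 100.0 * (n0 + (n1 - n0) * (rt - rt0) / (rt1 - rt0))


# ---------------------------------------------------------------------------
# fragment list I/O
# ---------------------------------------------------------------------------

def read_fragments(path) -> list[float]:
    """Read an MS2 fragment m/z list from an MGF file (first spectrum) or a
    two-column CSV (m/z, intensity; header optional)."""
    path = str(path)
    if path.lower().endswith(".mgf"):
        from pyteomics import mgf
        with mgf.read(path) as reader:
            spectrum = next(iter(reader))
        return [float(x) for x in spectrum["m/z array"]]
    out = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            try:
                out.append(float(row[0]))
            except ValueError:
                continue  # header line
    return out
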