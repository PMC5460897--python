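"""Per-residue ionization charges and peptide net charge.

The charge of an ionizable side chain at a given pH follows the
Henderson–Hasselbalch equation: a basic group carries a fractional charge
of ``+1 / (1 + 10**(pH - pKa))`` and an acidic group
``-1 / (1 + 10**(pKa - pH))``.  At the physiological pH of 7.4 used
throughout this package, Lys and Arg are essentially +1, Asp and Glu
essentially -1, Cys is weakly negative (-0.085) and His weakly positive
(+0.048).  The default pKa set was back-solved so that the fractional
charges at pH 7.4 match the conventional three-decimal values exactly;
it can be overridden per residue.

Two simplifications are exposed as modes because they change the window
statistics downstream:

* ``rounding`` — ``"integer"`` replaces each fractional charge by its
  nearest integer (K/R -> +1, D/E -> -1, everything else 0), which is the
  default for all window analyses; ``"three_decimals"`` keeps the
  fractional values.
* ``his_mode`` — histidine's effective pKa in an unfolded chain (~6.5)
  leaves it mostly neutral at pH 7.4, so the default rounds it to 0;
  ``"plus_one"`` forces +1 to match older analyses that counted His as
  basic.

Free-termini charges (alpha-amino +0.996, alpha-carboxyl -1.000) are off
by default and only apply to full-length proteins when enabled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping

logger = logging.getLogger(__name__)

Polarity = Literal["acid", "base"]

#: Back-solved pKa values reproducing the conventional fractional charges
#: at pH 7.4 to three decimals.  Overridable via ResidueChargeTable entries.
DEFAULT_PKA: dict[str, tuple[float, Polarity]] = {
    "K": (10.40, "base"),
    "R": (12.00, "base"),
    "H": (6.10, "base"),
    "E": (4.40, "acid"),
    "D": (3.90, "acid"),
    "C": (8.43, "acid"),
}

ALPHA_AMINO_PKA: tuple[float, Polarity] = (9.80, "base")
ALPHA_CARBOXYL_PKA: tuple[float, Polarity] = (3.10, "acid")

#: Ambiguity / non-standard codes that carry charge 0 with a warning.
AMBIGUOUS_RESIDUES = frozenset("BZXUOJ")

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class UnknownResidueError(ValueError):
    """Raised for symbols that are not amino-acid letters."""


def _hh_fraction(ph: float, pka: float, polarity: Polarity) -> float:
    if polarity == "base":
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    return -1.0 / (1.0 + 10.0 ** (pka - ph))


@dataclass(frozen=True)
class ResidueChargeTable:
    """Residue -> charge lookup at a fixed pH.

    Parameters
    ----------
    ph:
        Solvent pH; 7.4 by default (physiological).
    entries:
        Residue letter -> (pKa, polarity).  Defaults to the back-solved set.
    his_mode:
        ``"zero"`` (default) or ``"plus_one"``; only affects rounded charges.
    rounding:
        ``"integer"`` (default) or ``"three_decimals"``; selects which
        per-residue value :meth:`charge` and peptide sums use.
    include_termini:
        Add the alpha-amino / alpha-carboxyl charges to full-protein sums.
    """

    ph: float = 7.4
    entries: Mapping[str, tuple[float, Polarity]] = field(
        default_factory=lambda: dict(DEFAULT_PKA)
    )
    his_mode: Literal["zero", "plus_one"] = "zero"
    rounding: Literal["integer", "three_decimals"] = "integer"
    include_termini: bool = False
    nterm_pka: tuple[float, Polarity] = ALPHA_AMINO_PKA
    cterm_pka: tuple[float, Polarity] = ALPHA_CARBOXYL_PKA

    def with_options(self, **kwargs) -> "ResidueChargeTable":
        return replace(self, **kwargs)

    # -- per-residue -------------------------------------------------

    def fractional(self, residue: str) -> float:
        """Fractional Henderson–Hasselbalch charge, reported to 3 decimals."""
        return fractional_residue_charge(residue, self)

    def rounded(self, residue: str) -> int:
        return rounded_residue_charge(residue, self)

    def charge(self, residue: str) -> float | int:
        """Per-residue charge under the active rounding mode."""
        if self.rounding == "integer":
            return self.rounded(residue)
        return self.fractional(residue)

    # -- termini -----------------------------------------------------

    def nterm_charge(self) -> float | int:
        frac = round(_hh_fraction(self.ph, *self.nterm_pka), 3)
        return round(frac) if self.rounding == "integer" else frac

    def cterm_charge(self) -> float | int:
        frac = round(_hh_fraction(self.ph, *self.cterm_pka), 3)
        return round(frac) if self.rounding == "integer" else frac


#: Module-level default table: integer rounding, His = 0, termini excluded.
DEFAULT_TABLE = ResidueChargeTable()

#: Variant used for the fractional-charge comparison: three-decimal
#: charges with free-termini contributions included.
FRACTIONAL_TABLE = ResidueChargeTable(rounding="three_decimals", include_termini=True)


def _validate_residue(residue: str) -> str:
    if not isinstance(residue, str) or len(residue) != 1:
        raise UnknownResidueError(f"expected a single residue letter, got {residue!r}")
    upper = residue.upper()
    if not upper.isalpha():
        raise UnknownResidueError(f"not an amino-acid letter: {residue!r}")
    return upper


def fractional_residue_charge(residue: str, table: ResidueChargeTable = DEFAULT_TABLE) -> float:
    """Henderson–Hasselbalch fractional charge of one residue.

    Basic residues return ``+1/(1+10**(pH-pKa))``, acidic residues
    ``-1/(1+10**(pKa-pH))``, everything else exactly 0.  The result is
    rounded to three decimals, matching the precision the downstream
    fractional-mode analyses use.
    """
    upper = _validate_residue(residue)
    if upper in AMBIGUOUS_RESIDUES:
        logger.warning("ambiguous/non-standard residue %r treated as charge 0", residue)
        return 0.0
    if upper not in STANDARD_RESIDUES:
        raise UnknownResidueError(f"unknown residue letter: {residue!r}")
    entry = table.entries.get(upper)
    if entry is None:
        return 0.0
    pka, polarity = entry
    return round(_hh_fraction(table.ph, pka, polarity), 3)


def rounded_residue_charge(residue: str, table: ResidueChargeTable = DEFAULT_TABLE) -> int:
    """Nearest-integer charge in {-1, 0, +1}; His follows ``table.his_mode``."""
    upper = _validate_residue(residue)
    if upper == "H":
        return 1 if table.his_mode == "plus_one" else 0
    frac = fractional_residue_charge(upper, table)
    return int(round(frac))


def residue_charges(sequence: str, table: ResidueChargeTable = DEFAULT_TABLE) -> list[float | int]:
    """Per-residue charges for a sequence under the table's rounding mode."""
    return [table.charge(res) for res in sequence]


def peptide_net_charge(
    sequence: str,
    table: ResidueChargeTable = DEFAULT_TABLE,
    is_full_protein: bool = False,
) -> float | int:
    """Net charge of a peptide: the sum of its per-residue charges.

    When ``table.include_termini`` is set and the sequence is a
    full-length protein, the alpha-amino charge is added at the first
    position and the alpha-carboxyl charge at the last.
    """
    if not sequence:
        raise ValueError("cannot compute net charge of an empty sequence")
    total = sum(residue_charges(sequence, table))
    if table.include_termini and is_full_protein:
        total += table.nterm_charge() + table.cterm_charge()
    if table.rounding == "integer":
        return int(total)
    return round(total, 3)


def load_table_config(path: str | Path) -> ResidueChargeTable:
    """Build a charge table from a key=value config file.

    Recognised keys: ``ph``, ``his_mode``, ``rounding``,
    ``include_termini`` and per-residue pKa overrides ``pka_X`` (the
    polarity of an overridden residue is kept from the default table,
    new residues need ``pka_X = value,acid|base``).  Lines starting with
    ``#`` are ignored.
    """
    ph = 7.4
    his_mode: Literal["zero", "plus_one"] = "zero"
    rounding: Literal["integer", "three_decimals"] = "integer"
    include_termini = False
    entries = dict(DEFAULT_PKA)
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if key == "ph":
            ph = float(value)
        elif key == "his_mode":
            if value not in ("zero", "plus_one"):
                raise ValueError(f"invalid his_mode: {value}")
            his_mode = value  # type: ignore[assignment]
        elif key == "rounding":
            if value not in ("integer", "three_decimals"):
                raise ValueError(f"invalid rounding: {value}")
            rounding = value  # type: ignore[assignment]
        elif key == "include_termini":
            include_termini = value.lower() in ("1", "true", "yes", "on")
        elif key.startswith("pka_"):
            res = key[4:].upper()
            if "," in value:
                pka_s, pol = (s.strip() for s in value.split(",", 1))
                if pol not in ("acid", "base"):
                    raise ValueError(f"invalid polarity for {res}: {pol}")
                entries[res] = (float(pka_s), pol)  # type: ignore[assignment]
            elif res in entries:
                entries[res] = (float(value), entries[res][1])
            else:
                raise ValueError(f"polarity required for new residue {res}")
        else:
            raise ValueError(f"unknown config key: {key}")
    return ResidueChargeTable(
        ph=ph,
        entries=entries,
        his_mode=his_mode,
        rounding=rounding,
        include_termini=include_termini,
    )
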