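"""Reading, writing and validation of current-distance (I-z) curve ensembles.

An I-z curve is the probe current of an electrochemical scanning tunneling
microscope recorded against piezo displacement with the feedback loop off,
under bipotentiostatic control of the probe potential ``U_P`` and the sample
potential ``U_S`` (both vs. the Ag/AgCl (SSC) reference).  Curves are stored
in "ectsv", a plain-text dialect designed to be diff-able and round-trip
safe:

* header lines ``# key = value`` (keys: ``condition``, ``mode``, ``U_P_V``,
  ``U_S_V``, ``speed_nm_s``, ``set_point_A``, ``seed``),
* a two-column tab-separated body ``z_nm<TAB>I_A``,
* a ``# ---`` separator line between curves.

Units are fixed throughout the package: ``z`` in nm (0 at the set-point
position, increasing with retraction), ``I`` in A, potentials in V vs SSC.
Approach-mode curves are serialized sorted ascending in ``z`` like every
other curve; the ``mode`` flag tells consumers the physical sweep direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Union

import numpy as np

RETRACTION = "retraction"
APPROACH = "approach"
MODES = (RETRACTION, APPROACH)

DEFAULT_SET_POINT = 0.4e-9  # A, feedback current defining the z = 0 position
DEFAULT_SPEED = 12.0  # nm/s, piezo sweep speed

#: header keys of the ectsv dialect, in canonical writing order
HEADER_KEYS = ("condition", "mode", "U_P_V", "U_S_V", "speed_nm_s", "set_point_A", "seed")


class ECTSVError(ValueError):
    """Base class for curve I/O and validation failures."""


class ECTSVParseError(ECTSVError):
    """Malformed ectsv content; carries the 1-based offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EmptyTableError(ECTSVParseError):
    """File (or section) contained no data rows at all."""


class CurveValidationError(ECTSVError):
    """A curve violates an IZCurve invariant; names the curve and field."""

    def __init__(self, message: str, curve: int | None = None, fields: str | None = None):
        self.curve = curve
        self.fields = fields
        prefix = f"curve {curve}" if curve is not None else "curve"
        if fields:
            prefix += f", field '{fields}'"
        super().__init__(f"{prefix}: {message}")


@dataclass
class IZCurve:
    """One current-vs-distance record with electrode-potential metadata.

    Parameters
    ----------
    z
        Gap displacement from the set-point position, nm, strictly ascending.
    I
        Probe current, A.
    U_P, U_S
        Probe and sample potentials, V vs SSC.  The bias ``U_bias = U_P - U_S``
        is derived, never stored.
    mode
        ``"retraction"`` or ``"approach"`` (physical sweep direction; data are
        stored ascending in ``z`` either way).
    condition
        Free-text experimental label, e.g. ``"bare_gold"`` or ``"pCc1-hCc"``.
    speed
        Piezo sweep speed, nm/s.
    set_point
        Initial feedback current, A (0.4 nA in the reference acquisition).
    """

    z: np.ndarray
    I: np.ndarray
    U_P: float
    U_S: float
    mode: str = RETRACTION
    condition: str = "unknown"
    speed: float = DEFAULT_SPEED
    set_point: float = DEFAULT_SET_POINT

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.I = np.asarray(self.I, dtype=float)

    @property
    def U_bias(self) -> float:
        """Probe-sample bias U_P - U_S, V."""
        return self.U_P - self.U_S

    def __len__(self) -> int:
        return int(self.z.size)

    def validate(self, index: int | None = None) -> None:
        """Raise :class:`CurveValidationError` on any invariant violation."""
        if self.z.ndim != 1 or self.I.ndim != 1 or self.z.size != self.I.size:
            raise CurveValidationError("z and I must be 1-D and equally long",
                                       index, "z")
        if self.z.size < 16:
            raise CurveValidationError(f"curve has {self.z.size} points, need >= 16",
                                       index, "z")
        if not np.all(np.isfinite(self.z)):
            raise CurveValidationError("non-finite z values", index, "z")
        if not np.all(np.diff(self.z) > 0):
            raise CurveValidationError("z must be strictly ascending", index, "z")
        if not np.all(np.isfinite(self.I)):
            raise CurveValidationError("non-finite currents", index, "I")
        if self.mode not in MODES:
            raise CurveValidationError(f"unknown mode {self.mode!r}", index, "mode")
        if not (self.set_point > 0):
            raise CurveValidationError("set_point must be positive", index, "set_point")
        if self.mode == RETRACTION:
            if abs(self.I[0] - self.set_point) > 0.25 * self.set_point:
                raise CurveValidationError(
                    f"retraction curve starts at {self.I[0]:.3g} A, more than 25% "
                    f"away from the {self.set_point:.3g} A set point",
                    index, "I")
        if not (math.isfinite(self.U_P) and math.isfinite(self.U_S)):
            raise CurveValidationError("non-finite electrode potential", index, "U_P")


@dataclass
class CurveSet:
    """Ordered collection of :class:`IZCurve` plus generator/file provenance."""

    curves: list[IZCurve] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self) -> Iterator[IZCurve]:
        return iter(self.curves)

    def __getitem__(self, i) -> IZCurve:
        return self.curves[i]

    def validate(self) -> None:
        if not self.curves:
            raise CurveValidationError("CurveSet is empty")
        for i, c in enumerate(self.curves):
            c.validate(index=i)


def _format_float(v: float) -> str:
    return f"{v:.17g}"


def write_curve_table(curves: CurveSet, path: Union[str, Path]) -> Path:
    """Write a :class:`CurveSet` to ``path`` in the ectsv dialect.

    Full-precision floats are emitted so that a read/write round trip
    preserves every numeric field to better than 1e-12 relative.
    """
    curves.validate()
    path = Path(path)
    seed = curves.provenance.get("seed")
    lines: list[str] = []
    for i, c in enumerate(curves):
        if i:
            lines.append("# ---")
        lines.append(f"# condition = {c.condition}")
        lines.append(f"# mode = {c.mode}")
        lines.append(f"# U_P_V = {_format_float(c.U_P)}")
        lines.append(f"# U_S_V = {_format_float(c.U_S)}")
        lines.append(f"# speed_nm_s = {_format_float(c.speed)}")
        lines.append(f"# set_point_A = {_format_float(c.set_point)}")
        if seed is not None:
            lines.append(f"# seed = {seed}")
        for zi, Ii in zip(c.z, c.I):
            lines.append(f"{_format_float(zi)}\t{_format_float(Ii)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


_OPTIONAL_DEFAULTS: dict[str, Callable[[], object]] = {
    "condition": lambda: "unknown",
    "mode": lambda: RETRACTION,
    "U_P_V": lambda: 0.0,
    "U_S_V": lambda: 0.0,
    "speed_nm_s": lambda: DEFAULT_SPEED,
    "set_point_A": lambda: DEFAULT_SET_POINT,
}


def _finalize_section(headers: dict[str, str], rows: list[tuple[float, float]],
                      curve_index: int, defaulted: dict[int, list[str]],
                      seeds: set[str]) -> IZCurve:
    # a key written with an empty value counts as absent
    missing = [k for k in _OPTIONAL_DEFAULTS if headers.get(k) in (None, "")]
    if missing:
        defaulted[curve_index] = missing
    get = lambda k: headers.get(k) if headers.get(k) not in (None, "") else None
    if get("seed") is not None:
        seeds.add(headers["seed"])

    def fval(key: str) -> float:
        raw = get(key)
        return float(raw) if raw is not None else _OPTIONAL_DEFAULTS[key]()  # type: ignore[return-value]

    z = np.array([r[0] for r in rows])
    I = np.array([r[1] for r in rows])
    return IZCurve(
        z=z, I=I,
        U_P=fval("U_P_V"), U_S=fval("U_S_V"),
        mode=get("mode") or RETRACTION,
        condition=get("condition") or "unknown",
        speed=fval("speed_nm_s"),
        set_point=fval("set_point_A"),
    )


def read_curve_table(path: Union[str, Path]) -> CurveSet:
    """Read an ectsv file into a validated :class:`CurveSet`.

    Raises
    ------
    ECTSVParseError
        On a malformed header or data row (names the offending line).
    EmptyTableError
        If the file contains no data rows.
    CurveValidationError
        If any parsed curve violates an IZCurve invariant (names the curve).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    curves: list[IZCurve] = []
    headers: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    defaulted: dict[int, list[str]] = {}
    seeds: set[str] = set()

    def flush(lineno: int) -> None:
        nonlocal headers, rows
        if not rows:
            if headers:
                raise ECTSVParseError("curve section has headers but no data rows", lineno)
            return
        curves.append(_finalize_section(headers, rows, len(curves), defaulted, seeds))
        headers, rows = {}, []

    with path.open(encoding="utf-8") as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body == "---":
                    flush(lineno)
                    continue
                if "=" not in body:
                    raise ECTSVParseError(f"malformed header {line!r} (expected 'key = value')",
                                          lineno)
                key, _, value = body.partition("=")
                headers[key.strip()] = value.strip()
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ECTSVParseError(f"expected two numeric columns, got {line!r}", lineno)
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise ECTSVParseError(f"non-numeric data row {line!r}", lineno) from None
        flush(lineno)

    if not curves:
        raise EmptyTableError(f"{path} contains no data rows")

    provenance: dict = {"path": str(path)}
    if defaulted:
        provenance["defaulted"] = defaulted
    if len(seeds) == 1:
        provenance["seed"] = next(iter(seeds))
    cs = CurveSet(curves=curves, provenance=provenance)
    cs.validate()
    return cs
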