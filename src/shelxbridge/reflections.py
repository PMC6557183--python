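"""Reflection data: mmCIF ``_refln`` input, fixed-format .hkl output.

The SHELX .hkl file is a fixed-format text file descended from 80-column
punched cards, one reflection per line::

    HHHHKKKKLLLLRRRRRRRRSSSSSSSSBBBB

with h, k, l right-justified in four columns each, the datum R and its
standard uncertainty S in eight columns each, and an optional four-column
batch field B: now -1 for a free-R (cross-validation) reflection and +1 or
absent for working reflections.  The position of the decimal point decides
how R and S are read, so an explicit decimal point is always written.  The
file ends with an all-zero terminator record.  Whether R is an intensity or
an amplitude is declared by the final HKLF card of the .ins file (4 for I,
3 for F).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from gemmi import cif

from .errors import HklOverflowError, IncompleteDataError

__all__ = ["Reflection", "ReflectionSet", "read_refln_cif",
           "write_hkl_line", "write_hkl", "read_hkl"]

_INDEX_LIMIT = 999  # |h|,|k|,|l| must fit four columns with sign


@dataclass(frozen=True)
class Reflection:
    """One reflection: indices, datum R, uncertainty S, optional batch."""

    h: int
    k: int
    l: int
    value: float
    sigma: float
    batch: int | None = None  # -1 free-R; None/+1 working

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def is_free(self) -> bool:
        return self.batch == -1


@dataclass
class ReflectionSet:
    """A homogeneous set of reflections plus its HKLF declaration."""

    reflections: list[Reflection] = field(default_factory=list)
    data_kind: str = "intensity"  # or "amplitude"
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def hklf_code(self) -> int:
        return 4 if self.data_kind == "intensity" else 3

    @property
    def n_free(self) -> int:
        return sum(1 for r in self.reflections if r.is_free)

    def __len__(self) -> int:
        return len(self.reflections)


_STATUS_FREE = {"f"}
_STATUS_WORKING = {"o", "1"}  # observed / PDB_REDO-style working flag


def _find_loop(block, tags):
    cols = [block.find_loop(f"_refln.{t}") for t in tags]
    if all(len(c) == 0 for c in cols):
        cols = [block.find_loop(f"_refln_{t}") for t in tags]
    return cols


def read_refln_cif(stream) -> ReflectionSet:
    """Parse the ``_refln`` loop of an mmCIF reflection file.

    Measured intensities with uncertainties are preferred; amplitudes are
    the fallback.  Friedel-separated data (I+ / I-) are accepted only when
    both branches are present, and are written out as +h and -h records.
    Status codes: 'f' marks a free-R reflection (batch -1), 'o' a working
    reflection (batch absent); anything else (unmeasured, systematically
    absent, cut) is dropped and counted.
    """
    text = stream.read() if hasattr(stream, "read") else stream
    doc = cif.read_string(text)
    block = None
    for cand in doc:
        if len(cand.find_loop("_refln.index_h")) or \
                len(cand.find_loop("_refln_index_h")):
            block = cand
            break
    if block is None:
        return ReflectionSet()

    def col(tag):
        c = block.find_loop(f"_refln.{tag}")
        if len(c) == 0:
            c = block.find_loop(f"_refln_{tag}")
        return list(c) if len(c) else None

    h = col("index_h")
    k = col("index_k")
    l = col("index_l")
    status = col("status") or col("observed_status")
    n = len(h) if h else 0

    i_mean = col("intensity_meas")
    si_mean = col("intensity_sigma") or col("intensity_meas_sigma") or \
        col("intensity_sigm")
    f_mean = col("F_meas_au") or col("F_meas")
    sf_mean = col("F_meas_sigma_au") or col("F_meas_sigma")
    i_plus, si_plus = col("pdbx_I_plus"), col("pdbx_I_plus_sigma")
    i_minus, si_minus = col("pdbx_I_minus"), col("pdbx_I_minus_sigma")

    def usable(vals):
        return vals is not None and any(v not in ("?", ".") for v in vals)

    anomalous = False
    if usable(i_mean):
        if not usable(si_mean):
            raise IncompleteDataError(
                "intensities present but standard uncertainties missing")
        values, sigmas, kind = i_mean, si_mean, "intensity"
    elif usable(i_plus) or usable(i_minus):
        if not (usable(i_plus) and usable(i_minus)):
            raise IncompleteDataError(
                "only one Friedel branch present (I+ without I-)")
        if not (usable(si_plus) and usable(si_minus)):
            raise IncompleteDataError(
                "anomalous intensities present but uncertainties missing")
        anomalous = True
        kind = "intensity"
    elif usable(f_mean):
        if not usable(sf_mean):
            raise IncompleteDataError(
                "amplitudes present but standard uncertainties missing")
        values, sigmas, kind = f_mean, sf_mean, "amplitude"
    elif n == 0:
        return ReflectionSet()
    else:
        raise IncompleteDataError("no usable intensity or amplitude column")

    out = ReflectionSet(data_kind=kind)
    dropped = out.dropped
    for i in range(n):
        st = (status[i].strip("'\"").lower() if status else "o")
        if st in _STATUS_FREE:
            batch = -1
        elif st in _STATUS_WORKING:
            batch = None
        else:
            dropped[st] = dropped.get(st, 0) + 1
            continue
        hh, kk, ll = int(h[i]), int(k[i]), int(l[i])
        if anomalous:
            for sign, vcol, scol in ((1, i_plus, si_plus),
                                     (-1, i_minus, si_minus)):
                if vcol[i] in ("?", "."):
                    continue
                out.reflections.append(Reflection(
                    sign * hh, sign * kk, sign * ll,
                    float(vcol[i]), float(scol[i]), batch))
        else:
            if values[i] in ("?", "."):
                dropped["?"] = dropped.get("?", 0) + 1
                continue
            out.reflections.append(Reflection(
                hh, kk, ll, float(values[i]), float(sigmas[i]), batch))
    return out


def _format_value(value: float, width: int = 8) -> str:
    """Fixed-point text with an explicit decimal point, right-justified.

    Uses as many decimals as the value needs (at least one), dropping
    precision only when the field would overflow; raises when even one
    decimal place cannot fit.
    """
    for decimals in range(6, 0, -1):
        text = f"{value:.{decimals}f}"
        stripped = text.rstrip("0")
        if stripped.endswith("."):
            stripped += "0"
        if len(stripped) <= width and float(text) == float(stripped):
            text = stripped
        if len(text) <= width:
            return text.rjust(width)
    text = f"{value:.0f}."  # integral value: trailing point still explicit
    if len(text) <= width:
        return text.rjust(width)
    raise HklOverflowError(
        f"value {value!r} cannot fit {width} columns at minimum precision")


def write_hkl_line(r: Reflection) -> str:
    """Format one reflection as a 28- or 32-column fixed-format line."""
    for idx in (r.h, r.k, r.l):
        if abs(idx) > _INDEX_LIMIT:
            raise HklOverflowError(
                f"index {idx} of reflection ({r.h} {r.k} {r.l}) does not "
                f"fit four columns")
    line = f"{r.h:4d}{r.k:4d}{r.l:4d}"
    line += _format_value(r.value)
    line += _format_value(r.sigma)
    if r.batch is not None:
        line += f"{r.batch:4d}"
    return line


def write_hkl(reflection_set: ReflectionSet, sink) -> int:
    """Write all reflections plus the all-zero terminator; return the count.

    ``sink`` is a writable text stream.  Formatting errors are re-raised
    with the offending reflection identified.
    """
    count = 0
    for i, r in enumerate(reflection_set.reflections):
        try:
            sink.write(write_hkl_line(r) + "\n")
        except HklOverflowError as exc:
            raise HklOverflowError(
                f"reflection #{i + 1} ({r.h} {r.k} {r.l}): {exc}") from exc
        count += 1
    sink.write(write_hkl_line(Reflection(0, 0, 0, 0.0, 0.0)) + "\n")
    return count


def read_hkl(stream, data_kind: str = "intensity") -> ReflectionSet:
    """Parse fixed-format .hkl text back (round-trip checking)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out = ReflectionSet(data_kind=data_kind)
    for line in stream:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        h = int(line[0:4])
        k = int(line[4:8])
        l = int(line[8:12])
        value = float(line[12:20])
        sigma = float(line[20:28])
        batch_text = line[28:32].strip()
        batch = int(batch_text) if batch_text else None
        if h == k == l == 0:
            break
        if batch == 1:
            batch = None  # "+1 or absent" both mean working
        out.reflections.append(Reflection(h, k, l, value, sigma, batch))
    return out
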