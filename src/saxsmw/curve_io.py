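"""Read and write 1D small-angle scattering curves.

The on-disk format is the de-facto SAS standard: whitespace-separated ASCII
columns ``q  I(q)  [sigma(q)]`` with ``#`` comment lines, as used by SASBDB
downloads and most reduction pipelines.  Metadata round-trips through
``# key = value`` header lines.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

SCALE_TAGS = ("absolute", "relative", "unknown")

#: header tokens that declare the q unit as inverse nanometres
_NM_PATTERNS = re.compile(r"1/nm|nm\^?-1|nm-1|inverse\s*nm", re.IGNORECASE)


@dataclass
class ScatteringCurve:
    """A 1D scattering profile I(q).

    Parameters
    ----------
    q : array
        Scattering vector, strictly increasing, in 1/Angstrom.
    I : array
        Intensity; 1/cm on an absolute scale, otherwise arbitrary units.
    sigma : array, optional
        Point-wise intensity uncertainty (same units as ``I``).
    scale : {"absolute", "relative", "unknown"}
        Whether the intensity scale is a calibrated differential
        cross-section per unit volume.
    meta : dict
        Free-form metadata (concentration, ground truth of a simulation, ...).
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    scale: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or self.q.size == 0:
            raise ValueError("q must be a non-empty 1D array")
        if self.q.shape != self.I.shape:
            raise ValueError("q and I must have the same length")
        if not np.all(np.isfinite(self.q)) or not np.all(np.isfinite(self.I)):
            raise ValueError("q and I must be finite")
        if np.any(self.q <= 0):
            raise ValueError("q must be positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q in length")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where present")
        if self.scale not in SCALE_TAGS:
            raise ValueError(f"scale must be one of {SCALE_TAGS}")

    def __len__(self) -> int:
        return self.q.size

    def with_intensity(self, I, sigma=None, **changes) -> "ScatteringCurve":
        """Return a copy with replaced intensity (and optionally sigma)."""
        return replace(self, I=np.asarray(I, float), sigma=sigma, meta=dict(self.meta), **changes)

    def crop(self, q_lo: float = 0.0, q_hi: float = np.inf) -> "ScatteringCurve":
        m = (self.q >= q_lo) & (self.q <= q_hi)
        sigma = self.sigma[m] if self.sigma is not None else None
        return ScatteringCurve(self.q[m], self.I[m], sigma, self.scale, dict(self.meta))


def _parse_meta(comment_lines: list[str]) -> dict:
    meta = {}
    for line in comment_lines:
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, val = body.partition("=")
            key = key.strip()
            val = val.strip()
            if key and " " not in key:
                try:
                    meta[key] = float(val)
                except ValueError:
                    meta[key] = val
    return meta


def read_dat(
    path,
    dialect: str = "generic",
    q_unit: str | None = None,
    drop_nonpositive_tail: bool = False,
) -> ScatteringCurve:
    """Read an ASCII ``.dat`` scattering curve.

    Comment lines (``#``) are skipped; lines that do not parse as >=2 numbers
    (SASBDB files carry free-text headers without ``#``) are ignored.  If the
    header declares the q unit as 1/nm — or ``q_unit="nm"`` forces it — q is
    divided by 10 to convert to 1/Angstrom.

    Parameters
    ----------
    dialect : {"generic", "sasbdb"}
        ``sasbdb`` tolerates the un-commented prose headers of SASBDB
        downloads (the parsing is shared; the flag documents intent).
    drop_nonpositive_tail : bool
        Drop the trailing run of rows with non-finite or I <= 0 (noisy
        post-subtraction high-q tails); the number dropped is logged.
    """
    path = Path(path)
    if dialect not in ("generic", "sasbdb"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows, comments = [], []
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                comments.append(stripped)
                continue
            parts = stripped.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                comments.append("# " + stripped)
                continue
            if len(vals) >= 2:
                rows.append(vals[:3])
    if not rows:
        raise ValueError(f"{path}: no numeric data rows found")
    ncol = min(len(r) for r in rows)
    if ncol < 2:
        raise ValueError(f"{path}: need at least 2 numeric columns")
    data = np.array([r[:ncol] for r in rows], dtype=float)

    meta = _parse_meta(comments)
    header_text = "\n".join(comments)
    if q_unit is None:
        q_unit = "nm" if _NM_PATTERNS.search(header_text) else "angstrom"
    if q_unit not in ("angstrom", "nm"):
        raise ValueError("q_unit must be 'angstrom' or 'nm'")

    q = data[:, 0]
    if q_unit == "nm":
        q = q / 10.0
    I = data[:, 1]
    sigma = data[:, 2] if ncol >= 3 else None

    keep = np.ones(q.size, dtype=bool)
    if drop_nonpositive_tail:
        bad = ~np.isfinite(I) | (I <= 0)
        # strip only the contiguous bad run at the high-q end
        idx = q.size
        while idx > 0 and bad[idx - 1]:
            idx -= 1
        keep[idx:] = False
        if idx < q.size:
            log.info("read_dat: dropped %d non-positive tail rows", q.size - idx)
    good = keep & np.isfinite(q) & np.isfinite(I) & (q > 0)
    if sigma is not None:
        good &= np.isfinite(sigma) & (sigma > 0)
    q, I = q[good], I[good]
    if sigma is not None:
        sigma = sigma[good]
    if q.size >= 2 and np.any(np.diff(q) <= 0):
        raise ValueError(f"{path}: q is not strictly increasing after parsing")

    scale = meta.pop("scale", "unknown")
    if scale not in SCALE_TAGS:
        scale = "unknown"
    return ScatteringCurve(q, I, sigma, scale, meta)


def write_dat(curve: ScatteringCurve, path) -> None:
    """Write a curve as 2/3-column ASCII, metadata in ``# key = value`` lines."""
    if len(curve) == 0:
        raise ValueError("refusing to write an empty curve")
    path = Path(path)
    lines = ["# 1D scattering curve: q [1/A]  I(q)" + ("  sigma" if curve.sigma is not None else "")]
    lines.append(f"# scale = {curve.scale}")
    for key, val in curve.meta.items():
        if isinstance(val, float):
            lines.append(f"# {key} = {val!r}")
        else:
            lines.append(f"# {key} = {val}")
    cols = [curve.q, curve.I] + ([curve.sigma] if curve.sigma is not None else [])
    body = np.column_stack(cols)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, body, fmt="%.10e")
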