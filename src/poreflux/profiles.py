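"""Tabulated 1-D profiles along the pore axis (or any scalar coordinate).

A :class:`Profile1D` holds a function sampled on a strictly increasing grid
— a free-energy profile G(z) in kcal/mol, a diffusion profile D(z) in
Å²/ps, or a metadynamics free energy F(ρ) over density — with an optional
pointwise error band.  Profiles are written and read as TSV with a
commented header so they stay diff-able and language-neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Profile1D:
    """A tabulated profile value(z) with an optional error band.

    Parameters
    ----------
    z:
        Strictly increasing sample grid (Å for spatial profiles, Å⁻³ for
        density profiles).
    values:
        Profile values at ``z``.
    err:
        Optional pointwise error band (same shape as ``values``).
    units:
        ``(z_unit, value_unit)`` labels recorded in file headers.
    """

    z: np.ndarray
    values: np.ndarray
    err: np.ndarray | None = None
    units: tuple[str, str] = ("A", "value")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.z.ndim != 1 or self.z.shape != self.values.shape:
            raise ValueError("z and values must be 1-D arrays of equal length")
        if self.z.size < 2:
            raise ValueError("a profile needs at least two points")
        if not np.all(np.diff(self.z) > 0):
            raise ValueError("z grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")
        if self.err is not None:
            self.err = np.asarray(self.err, dtype=float)
            if self.err.shape != self.values.shape:
                raise ValueError("err must match values in shape")

    def __len__(self) -> int:
        return self.z.size

    def interp(self, z_new: np.ndarray) -> "Profile1D":
        """Linear interpolation onto a new grid (must lie within range)."""
        z_new = np.asarray(z_new, dtype=float)
        if z_new.min() < self.z[0] - 1e-9 or z_new.max() > self.z[-1] + 1e-9:
            raise ValueError("interpolation grid extends beyond the profile range")
        vals = np.interp(z_new, self.z, self.values)
        err = None if self.err is None else np.interp(z_new, self.z, self.err)
        return Profile1D(z_new, vals, err, units=self.units, meta=dict(self.meta))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.z[0]), float(self.z[-1])

    # ------------------------------------------------------------------ I/O

    def write_tsv(self, path) -> None:
        """Write as TSV with a commented header line naming the units."""
        cols = [self.z, self.values]
        names = [f"z_{self.units[0]}", f"value_{self.units[1]}"]
        if self.err is not None:
            cols.append(self.err)
            names.append("err")
        with open(path, "w") as fh:
            fh.write("# " + "\t".join(names) + "\n")
            for row in zip(*cols):
                fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def read_tsv(cls, path) -> "Profile1D":
        """Read a profile written by :meth:`write_tsv`.

        Malformed rows raise with the offending line number; a missing
        third column yields a profile without an error band.
        """
        z, vals, err = [], [], []
        units = ("A", "value")
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    names = line.lstrip("# ").split("\t")
                    if len(names) >= 2:
                        units = (
                            names[0].removeprefix("z_"),
                            names[1].removeprefix("value_"),
                        )
                    continue
                parts = line.split("\t")
                if len(parts) not in (2, 3):
                    raise ValueError(f"{path}: line {lineno}: expected 2 or 3 columns")
                try:
                    row = [float(p) for p in parts]
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: {exc}") from None
                z.append(row[0])
                vals.append(row[1])
                if len(row) == 3:
                    err.append(row[2])
        if err and len(err) != len(z):
            raise ValueError(f"{path}: error column present only on some rows")
        return cls(
            np.array(z),
            np.array(vals),
            np.array(err) if err else None,
            units=units,
        )


def common_grid(a: Profile1D, b: Profile1D, lo: float | None = None, hi: float | None = None) -> np.ndarray:
    """Union grid of two profiles restricted to their overlap (and [lo, hi])."""
    lo_ov = max(a.z[0], b.z[0]) if lo is None else lo
    hi_ov = min(a.z[-1], b.z[-1]) if hi is None else hi
    if hi_ov <= lo_ov:
        raise ValueError("profiles have no overlapping z range")
    grid = np.union1d(a.z, b.z)
    grid = grid[(grid >= lo_ov) & (grid <= hi_ov)]
    if grid.size == 0 or grid[0] > lo_ov:
        grid = np.concatenate(([lo_ov], grid))
    if grid[-1] < hi_ov:
        grid = np.concatenate((grid, [hi_ov]))
    return grid
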