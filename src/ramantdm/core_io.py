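"""Spectrum data model and delimited-text I/O.

A :class:`Spectrum` is one wavenumber axis plus one intensity vector and the
sample metadata needed downstream (donor sex, treatment code, spiked
concentration, replicate index, reference/sample role).  A
:class:`SpectraSet` groups spectra by ``sample_id`` and supports the
median-spectrum reduction used as the scatter-correction reference.

Two text dialects are supported:

* ``long_csv`` — one row per channel per spectrum, columns
  ``sample_id,replicate,wavenumber_cm1,intensity``, with a metadata sidecar
  ``samples.csv`` (``sample_id,sex,treatment,concentration_uM,role``).
* ``wide_csv`` — first column ``wavenumber_cm1``, one column per
  ``sample_id.replicate``; requires a shared axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AxisMismatchError,
    SpectraFormatError,
    SpectraIntegrityError,
    SpectraParseError,
)

SEX_LABELS = frozenset(
    {"female", "male", "pool_female", "pool_male", "pool_mixed", "unknown"}
)
TREATMENT_LABELS = frozenset({"none", "froz", "filt", "cent", "filt_cent"})
ROLE_LABELS = frozenset({"reference", "sample"})

#: relative tolerance when deciding two wavenumber axes are "the same"
AXIS_RTOL = 1e-9


@dataclass
class SampleMeta:
    """Per-spectrum metadata.

    ``concentration_uM`` is the *set* (spiked) piperacillin concentration and
    may be ``None`` for pure-matrix spectra of unknown content.  Unknown
    metadata fields read from a file survive round-trips in ``extra``.
    """

    sample_id: str
    sex: str = "unknown"
    treatment: str = "none"
    concentration_uM: float | None = None
    replicate: int = 1
    role: str = "sample"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in SEX_LABELS:
            raise SpectraIntegrityError(
                f"unknown sex label {self.sex!r}; allowed: {sorted(SEX_LABELS)}"
            )
        if self.treatment not in TREATMENT_LABELS:
            raise SpectraIntegrityError(
                f"unknown treatment code {self.treatment!r}; "
                f"allowed: {sorted(TREATMENT_LABELS)}"
            )
        if self.role not in ROLE_LABELS:
            raise SpectraIntegrityError(f"unknown role {self.role!r}")
        if self.replicate < 0:
            raise SpectraIntegrityError("replicate index must be >= 0")
        if self.concentration_uM is not None and self.concentration_uM < 0:
            raise SpectraIntegrityError("concentration_uM must be >= 0")


@dataclass
class Spectrum:
    """One Raman spectrum: wavenumber axis (cm^-1) + intensities (counts)."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: SampleMeta

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise SpectraFormatError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise SpectraFormatError(
                f"axis length {self.wavenumbers.size} != "
                f"intensity length {self.intensities.size}"
            )
        if self.wavenumbers.size < 2:
            raise SpectraFormatError("a spectrum needs at least 2 channels")
        d = np.diff(self.wavenumbers)
        if np.any(d <= 0):
            if np.any(d == 0) or np.unique(self.wavenumbers).size < self.wavenumbers.size:
                raise SpectraFormatError("duplicate wavenumber channels")
            # ingest unsorted data: sort, remember the original order
            order = np.argsort(self.wavenumbers)
            self.meta.extra.setdefault("original_order", order.tolist())
            self.wavenumbers = self.wavenumbers[order]
            self.intensities = self.intensities[order]

    @property
    def n_channels(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        """Copy sharing the axis and metadata with new intensities."""
        return Spectrum(self.wavenumbers.copy(), np.asarray(intensities, float),
                        replace(self.meta, extra=dict(self.meta.extra)))


def same_axis(a: np.ndarray, b: np.ndarray, rtol: float = AXIS_RTOL) -> bool:
    return a.shape == b.shape and np.allclose(a, b, rtol=rtol, atol=0.0)


@dataclass
class SpectraSet:
    """A collection of spectra grouped by ``sample_id``."""

    spectra: list[Spectrum]

    def __post_init__(self) -> None:
        seen = set()
        for s in self.spectra:
            key = (s.meta.sample_id, s.meta.replicate)
            if key in seen:
                raise SpectraIntegrityError(
                    f"duplicate (sample_id, replicate) pair {key}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    @property
    def grouping(self) -> dict[str, list[int]]:
        g: dict[str, list[int]] = {}
        for s in self.spectra:
            g.setdefault(s.meta.sample_id, []).append(s.meta.replicate)
        return g

    def groups(self) -> Iterator[tuple[str, list[Spectrum]]]:
        g: dict[str, list[Spectrum]] = {}
        for s in self.spectra:
            g.setdefault(s.meta.sample_id, []).append(s)
        yield from g.items()

    def group(self, sample_id: str) -> list[Spectrum]:
        out = [s for s in self.spectra if s.meta.sample_id == sample_id]
        if not out:
            raise KeyError(sample_id)
        return out

    def map_intensities(self, fn) -> "SpectraSet":
        """Apply ``fn(Spectrum) -> Spectrum`` to every member."""
        return SpectraSet([fn(s) for s in self.spectra])


def median_spectrum(group: Sequence[Spectrum]) -> Spectrum:
    """Channel-wise median over replicate spectra.

    An even replicate count takes the arithmetic mean of the two central
    values.  Metadata is inherited from the group with ``replicate`` set to 0.
    """
    if len(group) == 0:
        raise ValueError("median_spectrum needs at least one spectrum")
    axis = group[0].wavenumbers
    for s in group[1:]:
        if not same_axis(axis, s.wavenumbers):
            raise AxisMismatchError(
                f"replicates of {group[0].meta.sample_id!r} have mixed axes"
            )
    stacked = np.vstack([s.intensities for s in group])
    med = np.median(stacked, axis=0)
    meta = replace(group[0].meta, replicate=0, extra=dict(group[0].meta.extra))
    return Spectrum(axis.copy(), med, meta)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_META_COLUMNS = ["sample_id", "sex", "treatment", "concentration_uM", "role"]


def _parse_meta_table(path: Path) -> dict[str, dict]:
    df = pd.read_csv(path, dtype=str)
    if "sample_id" not in df.columns:
        raise SpectraFormatError(f"{path}: missing column 'sample_id'")
    out: dict[str, dict] = {}
    for i, row in df.iterrows():
        rec = {k: row[k] for k in df.columns if k != "sample_id"}
        conc = rec.pop("concentration_uM", None)
        if conc is not None and isinstance(conc, str) and conc.strip() != "":
            try:
                conc = float(conc)
            except ValueError as exc:
                raise SpectraParseError(
                    f"{path}: non-numeric concentration_uM at row {i}"
                ) from exc
        else:
            conc = None
        known = {
            "sex": rec.pop("sex", "unknown"),
            "treatment": rec.pop("treatment", "none"),
            "role": rec.pop("role", "sample"),
            "concentration_uM": conc,
        }
        extra = {k: v for k, v in rec.items() if isinstance(v, str) and v != ""}
        known["extra"] = extra
        out[str(row["sample_id"])] = known
    return out


def _meta_for(sample_id: str, meta_map: dict[str, dict] | None) -> dict:
    if meta_map and sample_id in meta_map:
        m = meta_map[sample_id]
        return dict(m, extra=dict(m.get("extra", {})))
    return {"sex": "unknown", "treatment": "none", "role": "sample",
            "concentration_uM": None, "extra": {}}


def _sidecar_path(path: Path, metadata_path: str | Path | None) -> Path | None:
    if metadata_path is not None:
        return Path(metadata_path)
    candidate = Path(path).parent / "samples.csv"
    return candidate if candidate.exists() else None


def read_spectra(
    path: str | Path,
    dialect: str = "long_csv",
    metadata_path: str | Path | None = None,
) -> SpectraSet:
    """Read a :class:`SpectraSet` from a delimited text file.

    Parameters
    ----------
    path:
        Data file.  Metadata are looked up in ``metadata_path`` or, if absent,
        in a ``samples.csv`` next to ``path``.
    dialect:
        ``"long_csv"`` or ``"wide_csv"`` (see module docstring).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta_map = None
    sidecar = _sidecar_path(path, metadata_path)
    if sidecar is not None:
        meta_map = _parse_meta_table(sidecar)

    if dialect == "long_csv":
        return _read_long(path, meta_map)
    if dialect == "wide_csv":
        return _read_wide(path, meta_map)
    raise ValueError(f"unknown dialect {dialect!r}")


def _numeric(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    # float() is correctly rounded, so full-precision decimal renderings
    # round-trip bit-exactly (pandas' fast parser is not)
    raw = df[col]
    out = np.empty(len(raw))
    for i, cell in enumerate(raw):
        if cell is None or (isinstance(cell, float) and math.isnan(cell)):
            raise SpectraParseError(
                f"{path}: empty cell in column {col!r} at data row {i}"
            )
        try:
            out[i] = float(cell)
        except (TypeError, ValueError) as exc:
            raise SpectraParseError(
                f"{path}: non-numeric value {cell!r} in column {col!r} "
                f"at data row {i}"
            ) from exc
    return out


def _read_long(path: Path, meta_map: dict | None) -> SpectraSet:
    df = pd.read_csv(path, dtype=str)
    for col in ("sample_id", "replicate", "wavenumber_cm1", "intensity"):
        if col not in df.columns:
            raise SpectraFormatError(f"{path}: missing column {col!r}")
    if len(df) == 0:
        return SpectraSet([])
    w = _numeric(df, "wavenumber_cm1", path)
    y = _numeric(df, "intensity", path)
    rep = _numeric(df, "replicate", path).astype(int)
    sid = df["sample_id"].to_numpy()
    keyed: dict[tuple[str, int], list[int]] = {}
    for i, (s, r) in enumerate(zip(sid, rep)):
        keyed.setdefault((str(s), int(r)), []).append(i)
    spectra = []
    for (s_id, r), idx in keyed.items():
        rows = np.asarray(idx)
        meta = SampleMeta(sample_id=s_id, replicate=r, **_meta_for(s_id, meta_map))
        spectra.append(Spectrum(w[rows], y[rows], meta))
    return SpectraSet(spectra)


def _read_wide(path: Path, meta_map: dict | None) -> SpectraSet:
    df = pd.read_csv(path, dtype=str)
    if "wavenumber_cm1" not in df.columns:
        raise SpectraFormatError(f"{path}: missing column 'wavenumber_cm1'")
    w = _numeric(df, "wavenumber_cm1", path)
    spectra = []
    for col in df.columns:
        if col == "wavenumber_cm1":
            continue
        if "." not in col:
            raise SpectraFormatError(
                f"{path}: wide column {col!r} must be 'sample_id.replicate'"
            )
        s_id, rep = col.rsplit(".", 1)
        try:
            rep_i = int(rep)
        except ValueError as exc:
            raise SpectraFormatError(
                f"{path}: non-integer replicate in column {col!r}"
            ) from exc
        y = _numeric(df, col, path)
        meta = SampleMeta(sample_id=s_id, replicate=rep_i, **_meta_for(s_id, meta_map))
        spectra.append(Spectrum(w, y, meta))
    return SpectraSet(spectra)


def _format_float(x: float) -> str:
    # repr() is the shortest decimal string that round-trips a binary64
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return repr(float(x))


def write_spectra(
    spectra_set: SpectraSet,
    path: str | Path,
    dialect: str = "long_csv",
    metadata_path: str | Path | None = None,
) -> None:
    """Write a :class:`SpectraSet` with bit-stable full-precision rendering.

    Spectra are ordered by (sample_id, replicate) and channels ascending so
    output is deterministic.  A metadata sidecar is written to
    ``metadata_path`` or ``samples.csv`` next to ``path``.
    """
    path = Path(path)
    ordered = sorted(
        spectra_set.spectra, key=lambda s: (s.meta.sample_id, s.meta.replicate)
    )
    if dialect == "long_csv":
        lines = ["sample_id,replicate,wavenumber_cm1,intensity"]
        for s in ordered:
            for w, y in zip(s.wavenumbers, s.intensities):
                lines.append(
                    f"{s.meta.sample_id},{s.meta.replicate},"
                    f"{_format_float(w)},{_format_float(y)}"
                )
    elif dialect == "wide_csv":
        if ordered:
            axis = ordered[0].wavenumbers
            for s in ordered[1:]:
                if not same_axis(axis, s.wavenumbers):
                    raise AxisMismatchError(
                        "wide_csv requires a shared wavenumber axis; "
                        "resample spectra to a common grid first"
                    )
        header = ["wavenumber_cm1"] + [
            f"{s.meta.sample_id}.{s.meta.replicate}" for s in ordered
        ]
        lines = [",".join(header)]
        if ordered:
            for i, w in enumerate(ordered[0].wavenumbers):
                row = [_format_float(w)] + [
                    _format_float(s.intensities[i]) for s in ordered
                ]
                lines.append(",".join(row))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n")

    sidecar = Path(metadata_path) if metadata_path else path.parent / "samples.csv"
    extra_keys = sorted({k for s in ordered for k in s.meta.extra if k != "original_order"})
    meta_lines = [",".join(_META_COLUMNS + extra_keys)]
    seen = set()
    for s in ordered:
        if s.meta.sample_id in seen:
            continue
        seen.add(s.meta.sample_id)
        conc = "" if s.meta.concentration_uM is None else _format_float(
            s.meta.concentration_uM
        )
        row = [s.meta.sample_id, s.meta.sex, s.meta.treatment, conc, s.meta.role]
        row += [str(s.meta.extra.get(k, "")) for k in extra_keys]
        meta_lines.append(",".join(row))
    sidecar.write_text("\n".join(meta_lines) + "\n")
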