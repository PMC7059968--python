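"""Longitudinal cohort container and delimited-text I/O.

A cohort is a set of animals, each with strictly increasing measurement
times (days since injection) and positive sizes, plus the group-level
injection conditions.  The interchange format is a delimited text file with
a mandatory header and columns ID, TIME, OBS (comma or tab separated,
autodetected); group metadata travels in ``#``-prefixed header lines so a
write/read round trip is lossless.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import InjectionSpec

__all__ = ["Cohort", "ParseError", "read_cohort", "write_cohort"]


class ParseError(ValueError):
    """Malformed cohort file; the message names the offending row."""


@dataclass
class Cohort:
    data: pd.DataFrame  # columns ID, TIME, OBS
    inj: InjectionSpec
    unit: str = "mm3"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        missing = {"ID", "TIME", "OBS"} - set(df.columns)
        if missing:
            raise ParseError(f"missing columns: {sorted(missing)}")
        self.data = df = df.reset_index(drop=True)
        if len(df) == 0:
            raise ParseError("cohort has no observations")
        if np.any(df["OBS"].to_numpy(dtype=float) <= 0):
            row = int(np.argmax(df["OBS"].to_numpy(dtype=float) <= 0))
            raise ParseError(f"non-positive OBS at row {row}")
        for animal, grp in df.groupby("ID", sort=False):
            t = grp["TIME"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ParseError(f"times not strictly increasing for animal {animal}")

    @property
    def ids(self):
        return list(dict.fromkeys(self.data["ID"]))

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def per_animal(self):
        """Yield (id, times, observations) per animal in file order."""
        for animal, grp in self.data.groupby("ID", sort=False):
            yield animal, grp["TIME"].to_numpy(float), grp["OBS"].to_numpy(float)

    def animal(self, animal_id):
        grp = self.data[self.data["ID"] == animal_id]
        if len(grp) == 0:
            raise KeyError(animal_id)
        return grp["TIME"].to_numpy(float), grp["OBS"].to_numpy(float)

    def drop_animal(self, animal_id) -> "Cohort":
        df = self.data[self.data["ID"] != animal_id]
        return Cohort(df.copy(), self.inj, self.unit, dict(self.meta))

    def flat_arrays(self):
        """(t, y, animal_index, n_animals) with a contiguous animal index."""
        ids = self.ids
        lookup = {a: i for i, a in enumerate(ids)}
        idx = self.data["ID"].map(lookup).to_numpy(dtype=np.int64)
        return (
            self.data["TIME"].to_numpy(float),
            self.data["OBS"].to_numpy(float),
            idx,
            len(ids),
        )


def write_cohort(cohort: Cohort, path, sep: str = ",") -> None:
    with open(path, "w") as fh:
        fh.write(f"# V_inj={cohort.inj.V_inj!r} unit={cohort.unit}\n")
        if cohort.inj.lambda_invitro is not None:
            fh.write(f"# lambda_invitro={cohort.inj.lambda_invitro!r}\n")
        cohort.data.to_csv(fh, sep=sep, index=False, columns=["ID", "TIME", "OBS"])


def _parse_meta(lines):
    meta = {}
    for line in lines:
        for tok in line.lstrip("#").split():
            if "=" in tok:
                key, val = tok.split("=", 1)
                try:
                    meta[key] = float(val)
                except ValueError:
                    meta[key] = val
    return meta


def read_cohort(path, V_inj: float | None = None, unit: str | None = None) -> Cohort:
    """Read a cohort file; V_inj/unit fall back to ``#`` header metadata."""
    with open(path) as fh:
        text = fh.read()
    header_lines = [l for l in text.splitlines() if l.startswith("#")]
    body = "\n".join(l for l in text.splitlines() if not l.startswith("#"))
    meta = _parse_meta(header_lines)
    try:
        df = pd.read_csv(io.StringIO(body), sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    df.columns = [str(c).strip().upper() for c in df.columns]
    missing = {"ID", "TIME", "OBS"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    for col in ("TIME", "OBS"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise ParseError(f"{path}: non-numeric {col} at row {row}")
        df[col] = coerced.astype(float)
    if V_inj is None:
        V_inj = meta.get("V_inj")
    if V_inj is None:
        raise ParseError(f"{path}: V_inj not given and not present in header metadata")
    unit = unit or meta.get("unit", "mm3")
    lam = meta.get("lambda_invitro")
    inj = InjectionSpec(float(V_inj), lambda_invitro=lam)
    return Cohort(df[["ID", "TIME", "OBS"]], inj, str(unit))
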