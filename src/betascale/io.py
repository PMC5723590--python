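"""Tabular I/O for stem maps, environment samples, result tables and run configuration.

All files are tab-separated UTF-8 text with a decimal point. The stem-map
file carries its plot dimensions in a leading ``#`` comment so that a file
is self-describing. Readers are strict: every rejected row is reported with
its (1-based) data row number, and nothing is dropped silently.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


class FormatError(ValueError):
    """A file does not conform to the documented column/layout contract."""


class ValidationError(ValueError):
    """A file parses but violates a domain invariant (range, duplicate, ...)."""


STEM_COLUMNS = ("x", "y", "species", "dbh")
SOIL_COLUMNS = ("cx", "cy", "om", "ph", "tn", "p", "k", "depth")
SOIL_VARS = ("om", "ph", "tn", "p", "k", "depth")
VERTEX_COLUMNS = ("vx", "vy", "elev")
FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class StemMap:
    """A stem-mapped tree community on a rectangular plot.

    Coordinates are meters from the plot's lower-left corner, half-open:
    ``0 <= x < plot_width`` and ``0 <= y < plot_height`` so that grain
    membership is unambiguous. Census rule: only stems with dbh >= 1 cm.
    """

    plot_width: float
    plot_height: float
    stems: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.stems, pd.DataFrame):
            self.stems = pd.DataFrame(self.stems, columns=list(STEM_COLUMNS))
        self.validate()

    @property
    def n_stems(self) -> int:
        return len(self.stems)

    @property
    def species(self) -> list[str]:
        return sorted(self.stems["species"].unique())

    def validate(self) -> None:
        missing = [c for c in STEM_COLUMNS if c not in self.stems.columns]
        if missing:
            raise FormatError(f"stem map missing column(s): {', '.join(missing)}")
        if self.plot_width <= 0 or self.plot_height <= 0:
            raise ValidationError("plot dimensions must be positive")
        if self.n_stems == 0:
            return
        x = self.stems["x"].to_numpy(float)
        y = self.stems["y"].to_numpy(float)
        bad = ~((x >= 0) & (x < self.plot_width) & (y >= 0) & (y < self.plot_height))
        if bad.any():
            rows = np.flatnonzero(bad)[:5] + 1
            raise ValidationError(
                f"stem coordinates outside [0,{self.plot_width}) x "
                f"[0,{self.plot_height}) at data row(s) {rows.tolist()}"
            )
        dbh = self.stems["dbh"].to_numpy(float)
        if (dbh < 1).any():
            rows = np.flatnonzero(dbh < 1)[:5] + 1
            raise ValidationError(f"dbh < 1 cm at data row(s) {rows.tolist()}")
        sp = self.stems["species"].astype(str)
        if (sp.str.len() == 0).any():
            rows = np.flatnonzero((sp.str.len() == 0).to_numpy())[:5] + 1
            raise ValidationError(f"empty species label at data row(s) {rows.tolist()}")


@dataclass
class EnvSampleTable:
    """Per-grain soil samples on the base (20 m) design plus vertex elevations.

    ``samples`` has one record per base grain keyed by the grain center
    (cx, cy); the six soil variables are the per-grain averages. Vertex
    elevations are the measured elevations of the base-grain corner lattice.
    """

    samples: pd.DataFrame
    vertex_elevations: pd.DataFrame | None = None
    base_grain: float = 20.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in SOIL_COLUMNS if c not in self.samples.columns]
        if missing:
            raise FormatError(f"environment table missing column(s): {', '.join(missing)}")
        for c in SOIL_COLUMNS:
            if not np.issubdtype(self.samples[c].dtype, np.number):
                raise FormatError(f"non-numeric value in column {c!r}")
        keys = list(zip(self.samples["cx"], self.samples["cy"]))
        if len(set(keys)) != len(keys):
            dupes = self.samples[self.samples.duplicated(["cx", "cy"], keep=False)]
            raise ValidationError(
                f"duplicate grain center(s): {sorted(set(zip(dupes.cx, dupes.cy)))[:5]}"
            )
        if (self.samples["ph"].to_numpy() < 0).any():
            raise ValidationError("negative pH")
        if (self.samples["depth"].to_numpy() <= 0).any():
            raise ValidationError("non-positive rootable depth")
        if self.vertex_elevations is not None:
            missing = [c for c in VERTEX_COLUMNS if c not in self.vertex_elevations.columns]
            if missing:
                raise FormatError(f"vertex table missing column(s): {', '.join(missing)}")

    def check_complete(self, plot_width: float, plot_height: float) -> None:
        """Verify one record per base grain; report the missing centers."""
        g = self.base_grain
        nx = int(plot_width // g)
        ny = int(plot_height // g)
        want = {
            (round(ix * g + g / 2, 6), round(iy * g + g / 2, 6))
            for ix in range(nx)
            for iy in range(ny)
        }
        have = {
            (round(float(a), 6), round(float(b), 6))
            for a, b in zip(self.samples["cx"], self.samples["cy"])
        }
        missing = sorted(want - have)
        if missing:
            raise ValidationError(
                f"{len(missing)} base grain(s) without a soil record, e.g. {missing[:5]}"
            )


@dataclass
class RunConfig:
    """Everything needed to reproduce a full multi-grain analysis run."""

    plot_width: float = 260.0
    plot_height: float = 200.0
    grain_sizes: tuple[float, ...] = (20.0, 30.0, 40.0, 50.0)
    n_perm: int = 999
    alpha: float = 0.05
    seed: int = 0
    env_method: str = "block_mean"
    use_ceiling: bool = True
    out_dir: str = "betascale_out"
    scenario: str | None = "mixed"
    stem_map_path: str | None = None
    env_path: str | None = None
    vertex_path: str | None = None

    def __post_init__(self) -> None:
        self.grain_sizes = tuple(float(g) for g in self.grain_sizes)
        if any(g <= 0 for g in self.grain_sizes):
            raise ValidationError("grain sizes must be positive")
        if any(g > min(self.plot_width, self.plot_height) for g in self.grain_sizes):
            raise ValidationError("grain size exceeds a plot dimension")
        if self.n_perm < 1:
            raise ValidationError("permutation count must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.env_method not in ("block_mean", "kriging"):
            raise ValidationError(f"unknown env_method {self.env_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["grain_sizes"] = list(self.grain_sizes)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_header_dims(path: Path) -> tuple[float, float]:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().strip()
    if not first.startswith("#"):
        raise FormatError(
            "stem-map file must start with a '# plot_width=... plot_height=...' comment"
        )
    kv = {}
    for token in first.lstrip("#").split():
        if "=" in token:
            k, v = token.split("=", 1)
            kv[k] = v
    try:
        return float(kv["plot_width"]), float(kv["plot_height"])
    except KeyError as exc:
        raise FormatError(f"stem-map header comment missing {exc}") from None


def read_stem_map(path: str | Path) -> StemMap:
    """Read a stem map TSV (columns x, y, species, dbh; dims in the header comment)."""
    path = Path(path)
    w, h = _read_header_dims(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"species": str})
    missing = [c for c in STEM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"stem map missing column(s): {', '.join(missing)}")
    df = df[list(STEM_COLUMNS)].astype({"x": float, "y": float, "dbh": float})
    return StemMap(w, h, df)


def write_stem_map(stem_map: StemMap, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# plot_width={stem_map.plot_width:g} plot_height={stem_map.plot_height:g}\n"
        )
        stem_map.stems.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    return path


def read_env_samples(
    path: str | Path,
    vertex_path: str | Path | None = None,
    plot_dims: tuple[float, float] | None = None,
    base_grain: float = 20.0,
) -> EnvSampleTable:
    """Read per-grain soil samples (and optionally the vertex elevation lattice).

    When ``plot_dims`` is given, completeness is enforced: every base grain
    must have exactly one record.
    """
    df = pd.read_csv(Path(path), sep="\t", comment="#")
    missing = [c for c in SOIL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"environment table missing column(s): {', '.join(missing)}")
    for c in SOIL_COLUMNS:
        if not np.issubdtype(df[c].dtype, np.number):
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna()][:5] + 1
            raise FormatError(f"non-numeric value in column {c!r} at data row(s) {list(bad)}")
    df = df.astype({c: float for c in SOIL_COLUMNS})
    vertices = None
    if vertex_path is not None:
        vertices = pd.read_csv(Path(vertex_path), sep="\t", comment="#")
        if all(c in vertices.columns for c in VERTEX_COLUMNS):
            vertices = vertices.astype({c: float for c in VERTEX_COLUMNS})
    table = EnvSampleTable(df, vertices, base_grain=base_grain)
    if plot_dims is not None:
        table.check_complete(*plot_dims)
    return table


def write_env_samples(table: EnvSampleTable, path: str | Path,
                      vertex_path: str | Path | None = None) -> Path:
    path = Path(path)
    table.samples.to_csv(path, sep="\t", index=False, float_format="%.10g")
    if vertex_path is not None and table.vertex_elevations is not None:
        table.vertex_elevations.to_csv(
            Path(vertex_path), sep="\t", index=False, float_format="%.10g"
        )
    return path


def write_results(tables: dict[str, pd.DataFrame], directory: str | Path) -> list[Path]:
    """Write each result table as ``<name>.tsv`` with fixed float precision.

    Column order is preserved as given (deterministic), floats use %.6g.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        p = directory / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format=FLOAT_FORMAT)
        paths.append(p)
    return paths


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back any table produced by :func:`write_results`."""
    return pd.read_csv(Path(path), sep="\t")
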