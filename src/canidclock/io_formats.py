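"""Readers and writers for the external formats the pipeline touches.

Covers CGmap per-cytosine methylation calls, sample metadata tables,
clock-model tables (the published canid/dog models ship with the package),
syntenic-coordinate mapping tables, and BED export/import.

Coordinates are 1-based throughout the package; the 0-based half-open
convention appears only at the BED boundary.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "SiteKey",
    "SampleMeta",
    "CountRecord",
    "ClockEntry",
    "ClockModel",
    "SyntenyMap",
    "read_cgmap",
    "write_cgmap",
    "read_metadata",
    "write_metadata",
    "read_clock_model",
    "write_clock_model",
    "load_packaged_clock",
    "read_synteny_map",
    "write_synteny_map",
    "write_bed",
    "read_bed",
]

VALID_SPECIES = frozenset({"dog", "wolf", "other"})
VALID_SEX = frozenset({"F", "M", "unknown"})


class CgmapParseError(ValueError):
    """A CGmap row could not be parsed or violates count invariants."""


class SchemaError(ValueError):
    """A delimited table is missing required columns or carries bad values."""


class SiteKey(NamedTuple):
    """A single CpG cytosine: assembly label, chromosome, 1-based position."""

    assembly: str
    chrom: str
    pos: int

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.assembly}:{self.chrom}:{self.pos}"


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: species, sex, chronological age, optional breed info."""

    sample_id: str
    species: str
    age_years: float
    sex: str = "unknown"
    breed: str | None = None
    breed_max_weight: float | None = None

    def __post_init__(self) -> None:
        if self.species not in VALID_SPECIES:
            raise SchemaError(
                f"sample {self.sample_id!r}: unknown species {self.species!r}"
            )
        if self.sex not in VALID_SEX:
            raise SchemaError(f"sample {self.sample_id!r}: unknown sex {self.sex!r}")
        if not self.age_years > 0:
            raise SchemaError(
                f"sample {self.sample_id!r}: age_years must be positive, "
                f"got {self.age_years}"
            )
        if self.breed_max_weight is not None:
            if self.species != "dog":
                raise SchemaError(
                    f"sample {self.sample_id!r}: breed_max_weight only valid for dogs"
                )
            if not self.breed_max_weight > 0:
                raise SchemaError(
                    f"sample {self.sample_id!r}: breed_max_weight must be positive"
                )


class CountRecord(NamedTuple):
    """Methylated (k) and total (t) mapped read counts at one site.

    t = 0 means the site is unobserved in this sample.
    """

    site: SiteKey
    k: int
    t: int


@dataclass(frozen=True)
class ClockEntry:
    """One CpG term of a clock model: coefficient plus training diagnostics."""

    site: SiteKey
    coef: float
    train_mean_meth: float | None = None
    train_age_corr: float | None = None


@dataclass
class ClockModel:
    """Sparse linear model of ln(age in years) on methylation fractions.

    Predicted age is exp(intercept + sum(coef * frequency)); the intercept is
    therefore on the log-years scale.
    """

    name: str
    assembly: str
    intercept: float
    entries: list[ClockEntry] = field(default_factory=list)
    age_transform: str = "log_e"

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            if e.site in seen:
                raise ValueError(f"duplicate site in clock model: {e.site}")
            seen.add(e.site)

    @property
    def sites(self) -> list[SiteKey]:
        return [e.site for e in self.entries]

    @property
    def n_cpgs(self) -> int:
        """Model size: number of nonzero non-intercept coefficients."""
        return sum(1 for e in self.entries if e.coef != 0.0)


@dataclass
class SyntenyMap:
    """A validated one-to-one pairing of sites between two assemblies."""

    pairs: list[tuple[SiteKey, SiteKey]]

    def __post_init__(self) -> None:
        if not self.pairs:
            self.assembly_a = None
            self.assembly_b = None
            return
        a_keys = [a for a, _ in self.pairs]
        b_keys = [b for _, b in self.pairs]
        assemblies_a = {a.assembly for a in a_keys}
        assemblies_b = {b.assembly for b in b_keys}
        if len(assemblies_a) != 1 or len(assemblies_b) != 1:
            raise SchemaError(
                "each side of a synteny map must be keyed to a single assembly; "
                f"got {sorted(assemblies_a)} vs {sorted(assemblies_b)}"
            )
        if len(set(a_keys)) != len(a_keys):
            raise SchemaError("duplicate site on the A side of the synteny map")
        if len(set(b_keys)) != len(b_keys):
            raise SchemaError("duplicate site on the B side of the synteny map")
        self.assembly_a = a_keys[0].assembly
        self.assembly_b = b_keys[0].assembly

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# CGmap
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_cgmap(path: str | Path, assembly: str = "canFam3") -> list[CountRecord]:
    """Read CpG-context rows of a CGmap file into count records.

    The 8-column CGmap dialect is expected: chrom, nucleotide (C/G), 1-based
    position, context (CG/CHG/CHH), dinucleotide context, methylation level,
    methylated count, total count. Non-CpG rows are skipped; the methylation
    level column is ignored (frequencies are recomputed downstream from k/t).
    """
    records: list[CountRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise CgmapParseError(
                    f"{path}: line {lineno}: expected 8 tab-delimited fields, "
                    f"got {len(fields)}"
                )
            chrom, _nuc, pos_s, context, _dinuc, _level, k_s, t_s = fields
            if context != "CG":
                continue
            try:
                pos, k, t = int(pos_s), int(k_s), int(t_s)
            except ValueError as exc:
                raise CgmapParseError(
                    f"{path}: line {lineno}: non-integer position or count"
                ) from exc
            if pos < 1:
                raise CgmapParseError(f"{path}: line {lineno}: position must be >= 1")
            if k < 0 or t < 0 or k > t:
                raise CgmapParseError(
                    f"{path}: line {lineno}: counts must satisfy 0 <= k <= t, "
                    f"got k={k}, t={t}"
                )
            records.append(CountRecord(SiteKey(assembly, chrom, pos), k, t))
    return records


def write_cgmap(records: Iterable[CountRecord], path: str | Path) -> None:
    """Write count records as CpG-context CGmap rows (level recomputed as k/t)."""
    with _open_text(path, "wt") as fh:
        for rec in records:
            level = rec.k / rec.t if rec.t > 0 else 0.0
            fh.write(
                f"{rec.site.chrom}\tC\t{rec.site.pos}\tCG\tCG\t"
                f"{level:.6g}\t{rec.k}\t{rec.t}\n"
            )


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

_META_REQUIRED = ("sample_id", "species", "age_years")


def read_metadata(path: str | Path, sep: str = "\t") -> list[SampleMeta]:
    """Read a delimited sample-metadata table into typed records."""
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    missing = [c for c in _META_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    out: list[SampleMeta] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        breed = d.get("breed")
        weight = d.get("breed_max_weight")
        out.append(
            SampleMeta(
                sample_id=str(d["sample_id"]),
                species=str(d["species"]),
                age_years=float(d["age_years"]),
                sex=str(d.get("sex", "unknown")) if pd.notna(d.get("sex", "unknown")) else "unknown",
                breed=None if breed is None or pd.isna(breed) else str(breed),
                breed_max_weight=None if weight is None or pd.isna(weight) else float(weight),
            )
        )
    return out


def write_metadata(meta: Sequence[SampleMeta], path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "species": [m.species for m in meta],
            "sex": [m.sex for m in meta],
            "age_years": [m.age_years for m in meta],
            "breed": [m.breed for m in meta],
            "breed_max_weight": [m.breed_max_weight for m in meta],
        }
    )
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Clock-model tables
# ---------------------------------------------------------------------------

_MODEL_COLUMNS = (
    "chrom",
    "pos",
    "coef",
    "mean_meth",
    "age_corr",
    "human_chrom",
    "human_pos",
    "proximal_genes",
)


def write_clock_model(model: ClockModel, path: str | Path) -> None:
    """Serialize a clock model in the published-table schema.

    First line is a header comment carrying assembly, intercept and the age
    transform; then a tab-delimited table of per-CpG rows.
    """
    with open(path, "w") as fh:
        fh.write(
            f"# assembly={model.assembly}\tintercept={model.intercept!r}\t"
            f"age_transform={model.age_transform}\n"
        )
        fh.write("\t".join(_MODEL_COLUMNS) + "\n")
        for e in model.entries:
            mean_s = "" if e.train_mean_meth is None else repr(e.train_mean_meth)
            corr_s = "" if e.train_age_corr is None else repr(e.train_age_corr)
            fh.write(
                f"{e.site.chrom}\t{e.site.pos}\t{e.coef!r}\t{mean_s}\t{corr_s}\t\t\t\n"
            )


def _parse_clock_table(text: str, name: str) -> ClockModel:
    buf = io.StringIO(text)
    header = buf.readline().strip()
    if not header.startswith("#"):
        raise SchemaError(f"clock table {name!r}: missing '#' header line")
    kv = dict(
        item.split("=", 1) for item in header.lstrip("#").strip().split("\t") if "=" in item
    )
    assembly = kv.get("assembly", "canFam3")
    intercept = float(kv["intercept"])
    age_transform = kv.get("age_transform", "log_e")
    df = pd.read_csv(buf, sep="\t", dtype={"chrom": str})
    missing = [c for c in ("chrom", "pos", "coef") if c not in df.columns]
    if missing:
        raise SchemaError(f"clock table {name!r}: missing column(s) {missing}")
    entries = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        mean_meth = d.get("mean_meth")
        age_corr = d.get("age_corr")
        entries.append(
            ClockEntry(
                site=SiteKey(assembly, str(d["chrom"]), int(d["pos"])),
                coef=float(d["coef"]),
                train_mean_meth=None if pd.isna(mean_meth) else float(mean_meth),
                train_age_corr=None if pd.isna(age_corr) else float(age_corr),
            )
        )
    return ClockModel(
        name=name,
        assembly=assembly,
        intercept=intercept,
        entries=entries,
        age_transform=age_transform,
    )


def read_clock_model(path: str | Path, name: str | None = None) -> ClockModel:
    path = Path(path)
    return _parse_clock_table(path.read_text(), name or path.stem)


PACKAGED_MODELS = ("canid", "dog")


def load_packaged_clock(name: str) -> ClockModel:
    """Load one of the published clock models shipped with the package.

    ``canid`` is the joint dog+wolf clock (intercept 4.382); ``dog`` the
    dog-only clock (intercept -6.9009). Both are on canFam3 coordinates and
    predict exp(linear predictor) years.
    """
    if name not in PACKAGED_MODELS:
        raise KeyError(
            f"unknown packaged clock {name!r}; available: {PACKAGED_MODELS}"
        )
    text = (
        resources.files("canidclock.data").joinpath(f"clock_{name}.tsv").read_text()
    )
    return _parse_clock_table(text, name)


# ---------------------------------------------------------------------------
# Synteny maps
# ---------------------------------------------------------------------------

_SYNTENY_COLUMNS = ("assembly_a", "chrom_a", "pos_a", "assembly_b", "chrom_b", "pos_b")


def read_synteny_map(path: str | Path, sep: str = "\t") -> SyntenyMap:
    """Read a delimited table of paired coordinates into a validated map."""
    df = pd.read_csv(path, sep=sep, dtype={"chrom_a": str, "chrom_b": str})
    missing = [c for c in _SYNTENY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    pairs = [
        (
            SiteKey(str(r.assembly_a), str(r.chrom_a), int(r.pos_a)),
            SiteKey(str(r.assembly_b), str(r.chrom_b), int(r.pos_b)),
        )
        for r in df.itertuples(index=False)
    ]
    return SyntenyMap(pairs)


def write_synteny_map(smap: SyntenyMap, path: str | Path, sep: str = "\t") -> None:
    rows = [
        (a.assembly, a.chrom, a.pos, b.assembly, b.chrom, b.pos)
        for a, b in smap.pairs
    ]
    pd.DataFrame(rows, columns=_SYNTENY_COLUMNS).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(sites: Sequence[SiteKey], path: str | Path) -> None:
    """Export 1-based site positions as 0-based half-open BED intervals."""
    assemblies = {s.assembly for s in sites}
    if len(assemblies) > 1:
        raise ValueError(f"mixed assemblies in BED export: {sorted(assemblies)}")
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos - 1}\t{s.pos}\n")


def read_bed(path: str | Path, assembly: str) -> list[SiteKey]:
    """Read single-base BED intervals back to 1-based site keys."""
    sites: list[SiteKey] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, start, end = line.split("\t")[:3]
            sites.append(SiteKey(assembly, chrom, int(start) + 1))
            if int(end) != int(start) + 1:
                raise ValueError(f"{path}: expected single-base intervals")
    return sites
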