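"""Study design: which libraries exist, their sex, stage and replicate index.

The reference layout is the eight-library sexed pre-blastoderm embryo design
(BJ1-BJ8): two sexes x two collection windows (2-3h and 3-5h after egg
laying) x two replicate pools. BJ1/BJ2 are male late, BJ3/BJ4 female late,
BJ5/BJ6 male early, BJ7/BJ8 female early.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import FormatError, ValidationError

SEXES = ("male", "female")
STAGES = ("early", "late")

#: accepted aliases for the stage column of a design table
_STAGE_ALIASES = {
    "early": "early",
    "late": "late",
    "2-3h": "early",
    "3-5h": "late",
}


@dataclass(frozen=True)
class Sample:
    id: str
    sex: str
    stage: str
    replicate: int
    library_size: Optional[float] = None
    include: bool = True

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sample {self.id!r}: unknown sex {self.sex!r}")
        if self.stage not in STAGES:
            raise ValidationError(f"sample {self.id!r}: unknown stage {self.stage!r}")
        if self.library_size is not None and self.library_size <= 0:
            raise ValidationError(f"sample {self.id!r}: library_size must be > 0")


@dataclass
class StudyDesign:
    """Ordered collection of samples with unique ids."""

    samples: list[Sample] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.samples]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate sample ids: {sorted(dupes)}")

    # -- lookups ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    def __len__(self) -> int:
        return len(self.samples)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.sample_ids

    def get(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.id == sample_id:
                return s
        raise KeyError(sample_id)

    def group(self, sex: str | None = None, stage: str | None = None) -> list[str]:
        """Sample ids matching the given sex and/or stage."""
        out = []
        for s in self.samples:
            if sex is not None and s.sex != sex:
                continue
            if stage is not None and s.stage != stage:
                continue
            out.append(s.id)
        return out

    def require_full_grid(self) -> None:
        """Full-screen mode needs every (sex, stage) cell to be non-empty."""
        for sex in SEXES:
            for stage in STAGES:
                if not self.group(sex=sex, stage=stage):
                    raise ValidationError(f"design has no {sex} {stage} sample")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "sex": [s.sex for s in self.samples],
                "stage": [s.stage for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
                "library_size": [s.library_size for s in self.samples],
            }
        ).set_index("sample_id")


def bj_design() -> StudyDesign:
    """The fixed eight-library BJ1-BJ8 reference design."""
    rows = [
        ("BJ1", "male", "late", 1),
        ("BJ2", "male", "late", 2),
        ("BJ3", "female", "late", 1),
        ("BJ4", "female", "late", 2),
        ("BJ5", "male", "early", 1),
        ("BJ6", "male", "early", 2),
        ("BJ7", "female", "early", 1),
        ("BJ8", "female", "early", 2),
    ]
    return StudyDesign([Sample(i, sex, st, r) for i, sex, st, r in rows])


_REQUIRED_COLS = ("sample_id", "sex", "stage", "replicate")


def read_design(path: str | Path) -> StudyDesign:
    """Read a design TSV (sample_id, sex, stage, replicate[, library_size]).

    Errors carry the 1-based line number of the offending record.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing design column(s) {missing}")
    samples: list[Sample] = []
    seen: set[str] = set()
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        sid = str(row.sample_id)
        if sid in seen:
            raise FormatError(f"{path}:{pos}: duplicate sample id {sid!r}")
        seen.add(sid)
        stage = _STAGE_ALIASES.get(str(row.stage).strip().lower())
        if stage is None:
            raise FormatError(f"{path}:{pos}: unknown stage token {row.stage!r}")
        sex = str(row.sex).strip().lower()
        if sex not in SEXES:
            raise FormatError(f"{path}:{pos}: unknown sex token {row.sex!r}")
        lib = None
        if "library_size" in df.columns:
            raw = getattr(row, "library_size")
            if raw is not None and str(raw) not in ("", "nan"):
                lib = float(raw)
        try:
            samples.append(Sample(sid, sex, stage, int(row.replicate), lib))
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}:{pos}: {exc}") from exc
    return StudyDesign(samples)


def write_design(design: StudyDesign, path: str | Path) -> None:
    from .cli_io import atomic_write_text  # local import avoids a cycle

    df = design.to_frame().reset_index()
    df["library_size"] = df["library_size"].map(
        lambda v: "" if v is None or pd.isna(v) else f"{v:.6g}"
    )
    atomic_write_text(path, df.to_csv(sep="\t", index=False))


def samples_subset(design: StudyDesign, ids: Iterable[str]) -> StudyDesign:
    ids = list(ids)
    unknown = [i for i in ids if i not in design]
    if unknown:
        raise ValidationError(f"unknown sample ids: {unknown}")
    return StudyDesign([design.get(i) for i in ids])
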