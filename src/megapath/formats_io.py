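"""Readers and writers for every on-disk format the pipeline touches.

All parsing-dialect decisions live here: expression matrices are
tab-separated gene-by-sample tables of log2 intensities with a companion
two-column sample->group map; gene sets use the standard GMT dialect
(name, description, members); literature relations are a five-column TSV
(regulator, target, polarity, disease_direction, n_refs).  No parser ever
drops a row silently -- every exclusion is logged with a reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTROL = "control"
CASE = "case"
GROUP_LABELS = frozenset({CONTROL, CASE})

POSITIVE = "positive"
NEGATIVE = "negative"

#: polarity spellings accepted on input; "-|" / "-+>" are the arrow glyphs
#: used in pathway diagrams for inhibition and stimulation.
POLARITY_ALIASES = {
    "positive": POSITIVE,
    "negative": NEGATIVE,
    "-+>": POSITIVE,
    "-|": NEGATIVE,
    "+": POSITIVE,
    "-": NEGATIVE,
}

UP = "up_in_disease"
DOWN = "down_in_disease"
PROMOTER = "promoter"
INHIBITOR = "inhibitor"
UNKNOWN = "unknown"
DISEASE_DIRECTIONS = frozenset({UP, DOWN, PROMOTER, INHIBITOR, UNKNOWN})


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass
class ExpressionStudy:
    """One case/control cohort: a log2 expression matrix plus metadata.

    Parameters
    ----------
    study_id : str
        Cohort identifier (e.g. a GEO series accession).
    matrix : pandas.DataFrame
        Genes (rows, unique identifiers) by samples (columns), log2 scale.
    sample_groups : pandas.Series
        Maps every sample column to ``"control"`` or ``"case"``.
    country : str
        Country of origin of the cohort.
    study_age : int
        Years since the study was deposited (>= 0).
    """

    study_id: str
    matrix: pd.DataFrame
    sample_groups: pd.Series
    country: str = ""
    study_age: int = 0

    def __post_init__(self) -> None:
        dup = self.matrix.index[self.matrix.index.duplicated()].unique().tolist()
        if dup:
            raise FormatError(
                f"study {self.study_id!r}: duplicated gene identifiers {dup}"
            )
        self.sample_groups = self.sample_groups.reindex(self.matrix.columns)
        missing = self.sample_groups.index[self.sample_groups.isna()].tolist()
        if missing:
            raise FormatError(
                f"study {self.study_id!r}: no group label for samples {missing}"
            )
        bad = sorted(set(self.sample_groups) - GROUP_LABELS)
        if bad:
            raise FormatError(
                f"study {self.study_id!r}: group labels outside "
                f"{{control, case}}: {bad}"
            )
        values = self.matrix.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError(f"study {self.study_id!r}: non-numeric matrix")
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"study {self.study_id!r}: non-finite value at gene "
                f"{self.matrix.index[r]!r}, sample {self.matrix.columns[c]!r}"
            )
        if self.n_control < 1 or self.n_case < 1:
            raise FormatError(
                f"study {self.study_id!r}: needs >=1 control and >=1 case "
                f"(got {self.n_control}/{self.n_case})"
            )
        if self.study_age < 0:
            raise FormatError(f"study {self.study_id!r}: negative study age")

    @property
    def n_control(self) -> int:
        return int((self.sample_groups == CONTROL).sum())

    @property
    def n_case(self) -> int:
        return int((self.sample_groups == CASE).sum())

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    def group_values(self, gene: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (control, case) log2 values for ``gene``."""
        if gene not in self.matrix.index:
            raise KeyError(f"gene {gene!r} not in study {self.study_id!r}")
        row = self.matrix.loc[gene]
        return (
            row[self.sample_groups == CONTROL].to_numpy(dtype=float),
            row[self.sample_groups == CASE].to_numpy(dtype=float),
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with an optional explicit background."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}
        if self.universe is not None:
            self.universe = frozenset(self.universe)
            for name, members in self.sets.items():
                stray = members - self.universe
                if stray:
                    raise FormatError(
                        f"set {name!r} has members outside the declared "
                        f"universe: {sorted(stray)[:5]}"
                    )

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)

    def background(self) -> frozenset[str]:
        """The enrichment background: explicit universe, else union of sets."""
        return self.universe if self.universe is not None else self.union()


@dataclass(frozen=True)
class RelationRecord:
    """A polarity-bearing literature relation regulator -> target."""

    regulator: str
    target: str
    polarity: str  # positive | negative
    disease_direction: str = UNKNOWN
    n_refs: int = 1

    def __post_init__(self) -> None:
        if self.polarity not in (POSITIVE, NEGATIVE):
            raise FormatError(f"unrecognized polarity {self.polarity!r}")
        if self.disease_direction not in DISEASE_DIRECTIONS:
            raise FormatError(
                f"unrecognized disease direction {self.disease_direction!r}"
            )
        if self.n_refs < 1:
            raise FormatError("n_refs must be >= 1")


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_study(
    path: str | Path,
    groups_path: str | Path,
    *,
    study_id: str | None = None,
    country: str = "",
    study_age: int = 0,
    assume_log2: bool = True,
) -> ExpressionStudy:
    """Read a TSV expression matrix plus its sample->group map.

    The matrix file has gene identifiers in the first column and one column
    per sample; the groups file has two columns (sample, group).  With
    ``assume_log2=False`` the values are treated as linear intensities and
    log2(x+1)-transformed on load.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str).str.strip()
    dup = raw.index[raw.index.duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"{path.name}: duplicated gene rows {dup}")
    # float() is correctly rounded (unlike pandas' fast parser), keeping
    # write->read bit-for-bit; the loop also pinpoints the offending cell
    columns = {}
    for col in raw.columns:
        values = np.empty(len(raw.index))
        for i, cell in enumerate(raw[col]):
            try:
                values[i] = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path.name}: non-numeric value {cell!r} at gene "
                    f"{raw.index[i]!r}, sample {col!r}"
                ) from None
        columns[col] = values
    matrix = pd.DataFrame(columns, index=raw.index)
    if not assume_log2:
        if (matrix.to_numpy() < 0).any():
            raise FormatError(f"{path.name}: negative intensity under --linear")
        matrix = np.log2(matrix + 1.0)

    groups = pd.read_csv(
        groups_path, sep="\t", header=None, names=["sample", "group"], dtype=str
    )
    groups["sample"] = groups["sample"].str.strip()
    groups["group"] = groups["group"].str.strip().str.lower()
    series = groups.set_index("sample")["group"]
    return ExpressionStudy(
        study_id=study_id or path.stem,
        matrix=matrix,
        sample_groups=series,
        country=country,
        study_age=study_age,
    )


def write_expression_study(
    study: ExpressionStudy, path: str | Path, groups_path: str | Path
) -> None:
    """Write the matrix and group map in the dialect `read_expression_study` reads."""
    # %.17g renders float64 exactly, so write->read is bit-for-bit
    study.matrix.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")
    study.sample_groups.to_frame().to_csv(
        groups_path, sep="\t", header=False
    )


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    Duplicate members within a line are de-duplicated with a warning; an
    empty file yields an empty collection.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{Path(path).name}:{lineno}: GMT line needs >=3 "
                    f"tab-separated fields, got {len(fields)}"
                )
            name, description, *members = fields
            members = [m.strip() for m in members if m.strip()]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.warning(
                    "%s:%d: set %r has duplicated members; de-duplicated",
                    Path(path).name, lineno, name,
                )
            sets[name] = frozenset(unique)
            descriptions[name] = description
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# literature relations


RELATION_COLUMNS = ["regulator", "target", "polarity", "disease_direction", "n_refs"]


def read_relation_table(path: str | Path) -> list[RelationRecord]:
    """Read a five-column relation TSV; rows without usable polarity are
    rejected and logged (only polarity-bearing relations are admitted)."""
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in RELATION_COLUMNS[:3] if c not in table.columns]
    if missing:
        raise FormatError(f"{Path(path).name}: missing columns {missing}")
    records: list[RelationRecord] = []
    for idx, row in table.iterrows():
        raw_pol = str(row["polarity"]).strip()
        polarity = POLARITY_ALIASES.get(raw_pol.lower())
        if polarity is None:
            logger.warning(
                "%s: row %d rejected: polarity %r is not recognized",
                Path(path).name, idx + 2, raw_pol,
            )
            continue
        direction = str(row.get("disease_direction", UNKNOWN) or UNKNOWN).strip().lower()
        if direction in ("", "nan"):
            direction = UNKNOWN
        if direction not in DISEASE_DIRECTIONS:
            logger.warning(
                "%s: row %d rejected: disease_direction %r unrecognized",
                Path(path).name, idx + 2, direction,
            )
            continue
        n_refs = int(float(row.get("n_refs", 1) or 1))
        records.append(
            RelationRecord(
                regulator=str(row["regulator"]).strip(),
                target=str(row["target"]).strip(),
                polarity=polarity,
                disease_direction=direction,
                n_refs=n_refs,
            )
        )
    return records


def write_relation_table(records: Iterable[RelationRecord], path: str | Path) -> None:
    rows = [
        {
            "regulator": r.regulator,
            "target": r.target,
            "polarity": r.polarity,
            "disease_direction": r.disease_direction,
            "n_refs": r.n_refs,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=RELATION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic tabular output


def write_results_table(
    records: Sequence[Mapping] | pd.DataFrame, path: str | Path
) -> None:
    """Write any uniform record collection as TSV with >=6 significant digits."""
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pd.DataFrame(list(records))
    frame.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_edge_list(edges: Iterable[tuple[str, int, str]], path: str | Path) -> None:
    """SIF-style edge list: geneA <TAB> weight <TAB> geneB."""
    with open(path, "w") as fh:
        for a, weight, b in edges:
            fh.write(f"{a}\t{weight}\t{b}\n")
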