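"""Binary toxin-family presence/absence matrices and their summaries.

A :class:`RepertoireMatrix` scores, for each toxin family (rows) and each
species (columns), whether at least one member of the family was
identified in that species' venom (proteome source) or venom-gland
transcriptome (transcriptome source).  Cells are present (1), absent (0),
or unknown (?).  Unknown cells are excluded from richness and sharing
summaries and widen to the full state set in parsimony analyses.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RepertoireMatrix",
    "SharingSpectrum",
    "read_matrix",
    "write_matrix",
    "species_richness",
    "order_sharing_spectrum",
    "unique_family_stats",
    "family_name_to_ascii",
    "family_name_from_ascii",
]

# Lossless Greek-letter aliasing for cross-platform file round-trips.
_GREEK_TO_ASCII = {"β": "beta-", "α": "alpha-", "γ": "gamma-", "δ": "delta-",
                   "ω": "omega-", "µ": "mu-", "μ": "mu-"}
_ASCII_TO_GREEK = {v: k for k, v in _GREEK_TO_ASCII.items() if k not in ("µ",)}


def family_name_to_ascii(name: str) -> str:
    for greek, ascii_ in _GREEK_TO_ASCII.items():
        if name.startswith(greek + "-"):
            return ascii_ + name[len(greek) + 1:]
        if name.startswith(greek):
            return ascii_ + name[len(greek):]
    return name


def family_name_from_ascii(name: str) -> str:
    for ascii_, greek in _ASCII_TO_GREEK.items():
        if name.startswith(ascii_):
            return greek + "-" + name[len(ascii_):]
    return name


@dataclass
class RepertoireMatrix:
    """Families x species binary matrix.

    ``data`` is a float DataFrame with values 1.0 (present), 0.0 (absent)
    and NaN (unknown); rows are families, columns species.
    """

    data: pd.DataFrame
    source: str = "proteome"

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate family names: {dupes}")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate species names")
        vals = self.data.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0) | (vals == 1)
        if not ok.all():
            r, c = np.argwhere(~ok)[0]
            raise ValueError(
                f"non-binary cell at family {self.data.index[r]!r}, "
                f"species {self.data.columns[c]!r}: {vals[r, c]!r}")
        empty = self.data.index[(self.data == 1).sum(axis=1) == 0].tolist()
        if empty:
            raise ValueError(
                f"families never present in any species: {empty}")

    @property
    def families(self) -> list[str]:
        return list(self.data.index)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    def character(self, family: str) -> dict[str, int | None]:
        """Species -> 0/1/None(unknown) for one family, as consumed by the
        parsimony engine."""
        row = self.data.loc[family]
        return {sp: (None if pd.isna(v) else int(v)) for sp, v in row.items()}

    def drop_species(self, species: str) -> "RepertoireMatrix":
        sub = self.data.drop(columns=[species])
        sub = sub[(sub == 1).sum(axis=1) > 0]
        return RepertoireMatrix(data=sub, source=self.source)


@dataclass
class SharingSpectrum:
    """Number of families found in exactly k distinct orders."""

    counts: dict[int, int] = field(default_factory=dict)

    @property
    def n_families(self) -> int:
        return sum(self.counts.values())

    def as_dict(self, max_k: int = 5) -> dict[int, int]:
        return {k: self.counts.get(k, 0) for k in range(1, max_k + 1)}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_CELL_MAP = {"0": 0.0, "1": 1.0, "?": np.nan}


def _parse_cells(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate family names: {dupes}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for c in df.columns:
        for r in df.index:
            raw = str(df.at[r, c]).strip()
            if raw in _CELL_MAP:
                out.at[r, c] = _CELL_MAP[raw]
            else:
                raise ValueError(
                    f"non-binary cell at row {r!r}, column {c!r}: {raw!r}")
    return out


def read_matrix(source: str | io.TextIOBase, source_kind: str = "proteome",
                orientation: str = "auto") -> RepertoireMatrix:
    """Read a presence/absence matrix from TSV/CSV or NEXUS.

    Canonical orientation is families as rows, species as columns.
    ``orientation="auto"`` transposes when there are more columns than
    rows (family counts dwarf species counts in repertoire data); use
    ``"families"``/``"species"`` to state what the rows are.
    """
    if isinstance(source, str) and source.lstrip().startswith("#NEXUS"):
        return _read_nexus_matrix(io.StringIO(source), source_kind)
    if isinstance(source, str):
        with open(source) as fh:
            head = fh.read(64)
        if head.lstrip().upper().startswith("#NEXUS"):
            with open(source) as fh:
                return _read_nexus_matrix(fh, source_kind)
        df = pd.read_csv(source, sep=None, engine="python", index_col=0,
                         dtype=str)
    else:
        text = source.read()
        if text.lstrip().upper().startswith("#NEXUS"):
            return _read_nexus_matrix(io.StringIO(text), source_kind)
        df = pd.read_csv(io.StringIO(text), sep=None, engine="python",
                         index_col=0, dtype=str)
    if orientation == "auto" and df.shape[1] > df.shape[0]:
        df = df.T
    elif orientation == "species":
        df = df.T
    df.index = [family_name_from_ascii(str(i)) for i in df.index]
    return RepertoireMatrix(data=_parse_cells(df), source=source_kind)


def _read_nexus_matrix(fh: io.TextIOBase, source_kind: str) -> RepertoireMatrix:
    """NEXUS DATA/CHARACTERS block: taxa as rows, families as CHARLABELS."""
    import dendropy

    text = fh.read()
    cmatrix = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    # dendropy drops CHARLABELS; recover them directly.
    m = re.search(r"CHARLABELS\s+(.*?);", text, re.IGNORECASE | re.DOTALL)
    nchar = max(len(cmatrix[t]) for t in cmatrix)
    if m:
        labels = re.findall(r"'([^']*)'|(\S+)", m.group(1))
        charlabels = [family_name_from_ascii(a or b) for a, b in labels]
    else:
        charlabels = [f"char{i + 1}" for i in range(nchar)]
    if len(charlabels) != nchar:
        raise ValueError("CHARLABELS count does not match NCHAR")
    cols: dict[str, list[float]] = {}
    for taxon in cmatrix:
        symbols = [str(s) for s in cmatrix[taxon].symbols_as_list()]
        cols[taxon.label] = [_CELL_MAP.get(s, np.nan) if s in _CELL_MAP
                             else np.nan for s in symbols]
        bad = [s for s in symbols if s not in _CELL_MAP]
        if bad:
            raise ValueError(
                f"non-binary cell for taxon {taxon.label!r}: {bad[0]!r}")
    df = pd.DataFrame(cols, index=charlabels)
    return RepertoireMatrix(data=df, source=source_kind)


def write_matrix(matrix: RepertoireMatrix, dest: str | io.TextIOBase,
                 fmt: str = "tsv") -> None:
    """Write TSV (families as rows) or a NEXUS CHARACTERS block."""
    if fmt == "tsv":
        df = matrix.data.copy()
        df.index = [family_name_to_ascii(f) for f in df.index]
        out = df.map(lambda v: "?" if pd.isna(v) else str(int(v)))
        text = out.to_csv(sep="\t", index_label="family")
    elif fmt == "nexus":
        taxa = matrix.species
        fams = [family_name_to_ascii(f) for f in matrix.families]
        lines = ["#NEXUS", "BEGIN DATA;",
                 f"DIMENSIONS NTAX={len(taxa)} NCHAR={len(fams)};",
                 'FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;',
                 "CHARLABELS " + " ".join(f"'{f}'" for f in fams) + ";",
                 "MATRIX"]
        for sp in taxa:
            col = matrix.data[sp]
            row = "".join("?" if pd.isna(v) else str(int(v)) for v in col)
            lines.append(f"{sp} {row}")
        lines += [";", "END;"]
        text = "\n".join(lines) + "\n"
    else:
        raise ValueError(f"unknown format: {fmt!r}")
    if isinstance(dest, str):
        with open(dest, "w") as fh:
            fh.write(text)
    else:
        dest.write(text)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def species_richness(matrix: RepertoireMatrix) -> dict[str, int]:
    """Number of families present in each species (unknowns excluded)."""
    counts = (matrix.data == 1).sum(axis=0)
    return {sp: int(counts[sp]) for sp in matrix.species}


def order_sharing_spectrum(matrix: RepertoireMatrix,
                           taxonomy: dict[str, str]) -> SharingSpectrum:
    """Distribution of families over the number of orders they occur in."""
    missing = [sp for sp in matrix.species if sp not in taxonomy]
    if missing:
        raise KeyError(f"species missing from taxonomy: {missing}")
    counts: dict[int, int] = {}
    for fam in matrix.families:
        row = matrix.data.loc[fam]
        orders = {taxonomy[sp] for sp in matrix.species if row[sp] == 1}
        k = len(orders)
        counts[k] = counts.get(k, 0) + 1
    return SharingSpectrum(counts=counts)


def unique_family_stats(matrix: RepertoireMatrix) -> dict[str, tuple[int, float]]:
    """Per species: (number of families unique to it, fraction of that
    species' families that are unique).  A family is unique to s when it
    is present in s and in no other species."""
    present = matrix.data == 1
    richness = present.sum(axis=0)
    row_totals = present.sum(axis=1)
    out: dict[str, tuple[int, float]] = {}
    for sp in matrix.species:
        uniq = int((present[sp] & (row_totals == 1)).sum())
        total = int(richness[sp])
        out[sp] = (uniq, uniq / total if total else 0.0)
    return out
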