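"""Readers and writers for the external formats the pipeline consumes.

Counts travel as TSV (genes x samples) with a separate sample-sheet TSV
declaring, for every column, which sucrose-gradient fraction it came from
(``cytoplasmic`` or ``polysomal``), the treatment condition (``NT`` or
``T``) and a replicate number.  5'UTR sequences travel as FASTA with the
convention that the first base of each record is the cap-adjacent +1
transcription-start base.  Dose-response matrices travel as CSV with drug-A
doses down the rows and drug-B doses across the columns, values normalized
so the untreated control equals 1.

No science lives here: every function either parses, validates, or
serializes.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("polyti")

FRACTIONS = ("cytoplasmic", "polysomal")
CONDITIONS = ("NT", "T")

_VALID_UTR_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """An input file violates the documented format contract."""


# ---------------------------------------------------------------------------
# count matrices + sample sheets
# ---------------------------------------------------------------------------

@dataclass
class CountDataset:
    """Gene x sample integer counts bound to a validated sample sheet.

    ``counts`` is a DataFrame (index = gene ids, columns = sample ids,
    dtype int64); ``sheet`` is a DataFrame indexed by sample id with
    columns ``fraction``, ``condition``, ``replicate``.
    """

    counts: pd.DataFrame
    sheet: pd.DataFrame

    def __post_init__(self) -> None:
        validate_sample_sheet(self.sheet)
        missing = [c for c in self.counts.columns if c not in self.sheet.index]
        if missing:
            raise FormatError(
                f"count-matrix column(s) not described in sample sheet: {missing}"
            )
        # keep sheet restricted to, and ordered like, the matrix columns
        self.sheet = self.sheet.loc[list(self.counts.columns)]
        self.counts.index.name = "gene_id"
        self.counts.columns = pd.Index(self.counts.columns, name="sample_id")
        self.sheet.index.name = "sample_id"

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def columns_for(self, fraction: str, condition: str | None = None) -> list[str]:
        """Sample ids belonging to a (fraction[, condition]) group."""
        mask = self.sheet["fraction"] == fraction
        if condition is not None:
            mask &= self.sheet["condition"] == condition
        return list(self.sheet.index[mask])


def validate_sample_sheet(sheet: pd.DataFrame) -> None:
    required = {"fraction", "condition", "replicate"}
    missing_cols = required - set(sheet.columns)
    if missing_cols:
        raise FormatError(f"sample sheet missing column(s): {sorted(missing_cols)}")
    if sheet.index.has_duplicates:
        dupes = sheet.index[sheet.index.duplicated()].tolist()
        raise FormatError(f"duplicate sample id(s): {dupes}")
    bad_frac = set(sheet["fraction"]) - set(FRACTIONS)
    if bad_frac:
        raise FormatError(f"unknown fraction value(s) {sorted(bad_frac)}; expected {FRACTIONS}")
    bad_cond = set(sheet["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise FormatError(f"unknown condition value(s) {sorted(bad_cond)}; expected {CONDITIONS}")
    reps = pd.to_numeric(sheet["replicate"], errors="coerce")
    if reps.isna().any() or (reps <= 0).any() or (reps % 1 != 0).any():
        raise FormatError("replicate must be a positive integer for every sample")
    for frac in FRACTIONS:
        for cond in CONDITIONS:
            n = ((sheet["fraction"] == frac) & (sheet["condition"] == cond)).sum()
            if n == 0:
                raise FormatError(f"no sample for group ({frac}, {cond})")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in sheet.columns:
        raise FormatError(f"{path}: sample sheet must have a 'sample_id' column")
    sheet = sheet.set_index("sample_id")
    validate_sample_sheet(sheet)
    return sheet


def read_count_matrix(path: str | Path, sheet_path: str | Path) -> CountDataset:
    """Read a counts TSV and its sample sheet into a :class:`CountDataset`.

    Every matrix column must appear in the sheet; cells must be
    non-negative integers.
    """
    sheet = read_sample_sheet(sheet_path)
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    for col in raw.columns:
        if col not in sheet.index:
            raise FormatError(f"{path}: column '{col}' absent from sample sheet")
    values = raw.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = raw.columns[[not np.issubdtype(d, np.number) for d in raw.dtypes]]
        raise FormatError(f"{path}: non-numeric counts in column(s) {list(bad)}")
    neg = np.argwhere(values < 0)
    if neg.size:
        g, s = neg[0]
        raise FormatError(
            f"{path}: negative count for gene '{raw.index[g]}', sample '{raw.columns[s]}'"
        )
    frac_part = np.argwhere(np.mod(values, 1) != 0)
    if frac_part.size:
        g, s = frac_part[0]
        raise FormatError(
            f"{path}: non-integer count for gene '{raw.index[g]}', sample '{raw.columns[s]}'"
        )
    return CountDataset(counts=raw.astype(np.int64), sheet=sheet)


def write_count_matrix(dataset: CountDataset, path: str | Path, sheet_path: str | Path) -> None:
    dataset.counts.to_csv(path, sep="\t", index_label="gene_id")
    dataset.sheet.to_csv(sheet_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# 5'UTR FASTA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UTRRecord:
    """A 5'UTR sequence; position 1 is the cap-adjacent (TSS) base."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty sequence for '{self.gene_id}'")
        bad = set(self.sequence) - _VALID_UTR_ALPHABET
        if bad:
            raise FormatError(
                f"invalid character(s) {sorted(bad)} in sequence of '{self.gene_id}'"
            )


def _normalize_sequence(raw: str, gene_id: str) -> str:
    seq = "".join(raw.split()).upper().replace("U", "T")
    if not seq:
        raise FormatError(f"empty sequence for record '{gene_id}'")
    return seq


def read_fasta_utrs(path: str | Path) -> list[UTRRecord]:
    """Read 5'UTRs; sequences are upper-cased, RNA mapped to DNA alphabet."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id.split()[0] if rec.id else ""
        if not gene_id:
            raise FormatError(f"{path}: FASTA record with empty header")
        records.append(UTRRecord(gene_id, _normalize_sequence(str(rec.seq), gene_id)))
    return records


def write_fasta_utrs(records: Iterable[UTRRecord], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.gene_id, description="") for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# dose-response matrices
# ---------------------------------------------------------------------------

@dataclass
class DoseMatrix:
    """Dose-combination response surface, control-normalized (untreated = 1).

    ``response[i, j]`` is the effect at dose ``doses_a[i]`` of drug A
    combined with ``doses_b[j]`` of drug B.  Loewe scoring requires the
    zero-dose margins (first row and column at dose 0) to be present.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        for name, doses in (("A", self.doses_a), ("B", self.doses_b)):
            if np.any(np.diff(doses) <= 0):
                raise FormatError(f"drug {name} doses not ascending: {doses.tolist()}")
            if np.any(doses < 0):
                raise FormatError(f"drug {name} doses must be non-negative")
        if self.response.shape != (len(self.doses_a), len(self.doses_b)):
            raise FormatError(
                f"response shape {self.response.shape} does not match "
                f"{len(self.doses_a)} x {len(self.doses_b)} dose grid"
            )
        if not self.has_zero_margins:
            logger.warning(
                "dose matrix lacks zero-dose margins; Loewe scoring will refuse it"
            )

    @property
    def has_zero_margins(self) -> bool:
        return self.doses_a[0] == 0.0 and self.doses_b[0] == 0.0


def read_dose_matrix(path: str | Path) -> DoseMatrix:
    frame = pd.read_csv(path, index_col=0)
    try:
        doses_a = frame.index.to_numpy(dtype=float)
        doses_b = frame.columns.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: dose labels must be numeric: {exc}") from exc
    return DoseMatrix(doses_a, doses_b, frame.to_numpy(dtype=float))


def write_dose_matrix(matrix: DoseMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(
        matrix.response,
        index=pd.Index(matrix.doses_a, name="dose_a"),
        columns=matrix.doses_b,
    )
    frame.to_csv(path, float_format="%.12g")


# ---------------------------------------------------------------------------
# gene lists, config, manifests
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list, one id per line; blank lines and '#' comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + ("\n" if genes else ""))


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg


def write_manifest(path: str | Path, command: str, params: dict,
                   inputs: dict | None = None, outputs: dict | None = None) -> None:
    """Machine-readable record of a run: command, parameters, inputs, versions.

    Deliberately timestamp-free so identical runs produce identical files.
    """
    from polyti import __version__

    manifest = {
        "command": command,
        "parameters": params,
        "inputs": inputs or {},
        "outputs": outputs or {},
        "versions": {
            "polyti": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
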