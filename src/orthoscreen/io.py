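"""Readers and writers for every pipeline format.

All tabular outputs are headered, tab-separated, UTF-8, LF-terminated;
floats are serialized with 12 significant digits so that re-running a
pipeline from the same inputs reproduces every file byte for byte.
Cluster files follow the OrthoMCL ``groups.txt`` convention.
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from pathlib import Path

from .align import HitTable, InputError, SimilarityHit
from .mcl import ClusterSet
from .simulate import FamilyTruthTable, GOAnnotationTable, StageExpressionTable

HIT_COLUMNS = ("qseqid", "sseqid", "pident", "length", "qlen", "slen",
               "qcovs", "scovs", "score", "bitscore", "evalue")


def _fmt(x: float) -> str:
    return f"{x:.12g}"


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    """Parse a protein FASTA file into an ordered {id: sequence} dict.

    Wrapped lines are joined; a trailing '*' stop is stripped with a
    warning; duplicate ids and empty sequences are errors.
    """
    path = Path(path)
    records: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []

    def flush():
        if current is None:
            return
        seq = "".join(chunks).upper()
        if seq.endswith("*"):
            warnings.warn(f"stripped trailing stop '*' from record {current!r}")
            seq = seq[:-1]
        if not seq:
            raise InputError(f"empty sequence for record {current!r} in {path}")
        records[current] = seq

    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                current = line[1:].split()[0]
                if not current:
                    raise InputError(f"header with no id in {path}")
                if current in records:
                    raise InputError(f"duplicate FASTA id {current!r} in {path}")
                chunks = []
            elif line:
                if current is None:
                    raise InputError(f"sequence before first header in {path}")
                chunks.append(line.strip())
        flush()
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def write_fasta(proteome: dict[str, str], path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for pid in proteome:
            fh.write(f">{pid}\n")
            seq = proteome[pid]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ------------------------------------------------------------- hit TSV

def write_hits_tsv(hits: HitTable, path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(HIT_COLUMNS)
        for h in hits:
            w.writerow([
                h.query_id, h.subject_id, _fmt(h.percent_identity),
                h.length, h.qlen, h.slen, _fmt(h.query_coverage),
                _fmt(h.subject_coverage), _fmt(h.raw_score),
                _fmt(h.bitscore), _fmt(h.evalue),
            ])


def read_hits_tsv(path, species_of: dict[str, str] | None = None) -> HitTable:
    """Read an outfmt-6-like hit TSV (the 11 pipeline columns).

    If *species_of* is not given, species tags are taken from the id
    prefix before the first ``|``.
    """
    path = Path(path)
    rows = []
    with path.open(newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r, None)
        if header is None or tuple(header) != HIT_COLUMNS:
            raise InputError(f"{path}: expected header {HIT_COLUMNS}")
        for i, row in enumerate(r, start=2):
            if len(row) != len(HIT_COLUMNS):
                raise InputError(f"{path}:{i}: expected {len(HIT_COLUMNS)} columns")
            rows.append(row)
    if species_of is None:
        species_of = {}
        for row in rows:
            for pid in row[:2]:
                if "|" not in pid:
                    raise InputError(
                        f"cannot infer species for {pid!r}: no 'sp|' prefix")
                species_of[pid] = pid.split("|", 1)[0]
    table = HitTable(species_of)
    for row in rows:
        table.add(SimilarityHit(
            query_id=row[0], subject_id=row[1],
            percent_identity=float(row[2]), length=int(row[3]),
            qlen=int(row[4]), slen=int(row[5]),
            query_coverage=float(row[6]), subject_coverage=float(row[7]),
            raw_score=float(row[8]), bitscore=float(row[9]),
            evalue=float(row[10]),
        ))
    return table


# ---------------------------------------------------------- groups.txt

def write_groups(clusters: ClusterSet, path) -> None:
    """OrthoMCL groups format plus a ``.singletons`` side file."""
    path = Path(path)
    with path.open("w") as fh:
        for cid, members in clusters.clusters.items():
            fh.write(f"{cid}: " + " ".join(members) + "\n")
    with path.with_suffix(path.suffix + ".singletons").open("w") as fh:
        for pid in clusters.singletons:
            fh.write(pid + "\n")


def read_groups(path) -> ClusterSet:
    path = Path(path)
    clusters: dict[str, tuple[str, ...]] = {}
    with path.open() as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if ":" not in line:
                raise InputError(f"{path}:{i}: malformed groups line (no colon)")
            cid, _, rest = line.partition(":")
            members = tuple(rest.split())
            if not members:
                raise InputError(f"{path}:{i}: cluster {cid!r} has no members")
            clusters[cid.strip()] = members
    single_path = path.with_suffix(path.suffix + ".singletons")
    singletons: tuple[str, ...] = ()
    if single_path.exists():
        singletons = tuple(
            ln.strip() for ln in single_path.read_text().splitlines() if ln.strip())
    return ClusterSet(clusters=clusters, singletons=singletons)


# ------------------------------------------------------------ GO / stage

def write_go_tsv(annotations: GOAnnotationTable, path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(("protein_id", "term_id"))
        for pid, term in annotations.rows:
            w.writerow((pid, term))


def read_go_tsv(path) -> GOAnnotationTable:
    rows = []
    with Path(path).open(newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r, None)
        if header != ["protein_id", "term_id"]:
            raise InputError(f"{path}: expected header protein_id/term_id")
        for row in r:
            rows.append((row[0], row[1]))
    return GOAnnotationTable(rows=sorted(set(rows)))


def write_stage_tsv(stage_table: StageExpressionTable, path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(("gene_id", "stage", "elevated"))
        for gene, stage, elevated in stage_table.records:
            w.writerow((gene, stage, int(elevated)))


def read_stage_tsv(path, n_stages: int = 10) -> StageExpressionTable:
    records = []
    with Path(path).open(newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r, None)
        if header != ["gene_id", "stage", "elevated"]:
            raise InputError(f"{path}: expected header gene_id/stage/elevated")
        for row in r:
            records.append((row[0], int(row[1]), bool(int(row[2]))))
    return StageExpressionTable(records=sorted(records), n_stages=n_stages)


# ----------------------------------------------------------- truth table

def write_truth_tsv(truth: FamilyTruthTable, path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(("family_id", "birth_branch", "lost_branches",
                    "members", "divergent"))
        for row in truth.to_rows():
            w.writerow((row["family_id"], row["birth_branch"],
                        row["lost_branches"], row["members"], row["divergent"]))


def read_truth_tsv(path, tree=None) -> FamilyTruthTable:
    rows = []
    with Path(path).open(newline="") as fh:
        r = csv.DictReader(fh, delimiter="\t")
        for row in r:
            rows.append(row)
    return FamilyTruthTable.from_rows(rows, tree)


# ------------------------------------------------------------- reports

def write_json(obj, path) -> None:
    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_tsv_rows(rows: list[dict], columns: list[str], path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(columns)
        for row in rows:
            w.writerow([
                _fmt(row[c]) if isinstance(row[c], float) else row[c]
                for c in columns
            ])


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
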