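"""File formats: PDB traces, FASTA-like letter sequences, TSV tables,
YAML run configuration.

Conventions: residue coordinates are 1-based inclusive in every file
written or read here; letter sequences are FASTA-like records with
headers ``>{protein_id}_{chain_id}/{segment_index}``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import pandas as pd
import yaml
from Bio.PDB import PDBParser

from .alphabet import LetterSequence
from .annotate import AnnotationRecord
from .geometry import CaTrace
from .loops import LoopSequence


def read_ca_traces(path: str | Path, protein_id: str | None = None) -> list[CaTrace]:
    """Cα traces from a PDB file, one per chain.

    Keeps ATOM records with atom name CA and blank or 'A' altloc;
    insertion codes are retained in the residue ids.
    """
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate sloppy records
        structure = PDBParser(QUIET=True).get_structure(protein_id, str(path))
    traces = []
    model = next(structure.get_models())
    for chain in model:
        residue_ids, coords = [], []
        for res in chain:
            het, resseq, icode = res.id
            if het.strip():
                continue
            if "CA" not in res:
                continue
            atom = res["CA"]
            if atom.is_disordered():
                try:
                    atom = atom.disordered_get("A")
                except Exception:
                    continue
            altloc = atom.get_altloc().strip()
            if altloc not in ("", "A"):
                continue
            residue_ids.append(f"{resseq}{icode.strip()}")
            coords.append(atom.coord)
        if coords:
            traces.append(
                CaTrace(
                    protein_id=protein_id,
                    chain_id=chain.id.strip() or "A",
                    residue_ids=residue_ids,
                    coords=coords,
                )
            )
    return traces


# ---- FASTA-like letter sequences ----


def write_letter_sequences(seqs: list[LetterSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.protein_id}_{s.chain_id}/{s.segment_index}\n{s.letters}\n")


def read_letter_sequences(path: str | Path) -> list[LetterSequence]:
    out = []
    header = None
    body: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                out.append(_make_seq(header, "".join(body)))
            header, body = line[1:], []
        else:
            body.append(line)
    if header is not None:
        out.append(_make_seq(header, "".join(body)))
    return out


def _make_seq(header: str, letters: str) -> LetterSequence:
    name, _, seg = header.partition("/")
    pid, _, chain = name.rpartition("_")
    if not pid:
        pid, chain = name, "A"
    return LetterSequence(
        protein_id=pid,
        chain_id=chain,
        letters=letters,
        residue_anchor=list(range(len(letters))),
        segment_index=int(seg) if seg.isdigit() else 0,
    )


# ---- TSV tables ----


def read_groups(path: str | Path) -> dict[str, str]:
    """protein_id → group_id from a two-column TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["protein_id", "group_id"]:
        df = pd.read_csv(path, sep="\t", dtype=str, header=None, names=["protein_id", "group_id"])
    if df.empty:
        raise ValueError(f"group table {path} is empty")
    return dict(zip(df["protein_id"], df["group_id"]))


def write_groups(mapping: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(mapping.items()), columns=["protein_id", "group_id"]
    ).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "chain_id", "residue_start", "residue_end", "feature_key"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return [
        AnnotationRecord(
            protein_id=r.protein_id,
            chain_id=r.chain_id,
            residue_start=int(r.residue_start),
            residue_end=int(r.residue_end),
            feature_key=r.feature_key,
            description=getattr(r, "description", "") or "",
        )
        for r in df.itertuples()
    ]


def write_annotations(annotations: list[AnnotationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "protein_id": a.protein_id,
                "chain_id": a.chain_id,
                "residue_start": a.residue_start,
                "residue_end": a.residue_end,
                "feature_key": a.feature_key,
                "description": a.description,
            }
            for a in annotations
        ],
        columns=[
            "protein_id",
            "chain_id",
            "residue_start",
            "residue_end",
            "feature_key",
            "description",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_loops(loops: list[LoopSequence], path: str | Path) -> None:
    from .loops import loops_to_frame

    loops_to_frame(loops).to_csv(path, sep="\t", index=False)


def read_loops(path: str | Path) -> list[LoopSequence]:
    df = pd.read_csv(path, sep="\t", dtype={"letters": str})
    out = []
    for r in df.itertuples():
        start = int(r.start_letter)
        out.append(
            LoopSequence(
                protein_id=str(r.protein_id),
                chain_id=str(r.chain_id),
                letters=str(r.letters),
                letter_positions=list(range(start, start + len(str(r.letters)))),
                residue_span=(int(r.residue_start), int(r.residue_end)),
                loop_id=str(r.loop_id),
                group_id="" if pd.isna(r.group_id) else str(r.group_id),
            )
        )
    return out


# ---- configuration ----


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
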