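"""File formats: FASTA, MEME minimal motif format, and the pipeline TSVs.

Conventions: TSVs are tab-separated with a header row; beta-value and
expression matrices put row IDs in the first column; motif offsets inside
sequences are 0-based while any genomic coordinates in annotations are
1-based inclusive.  All writers produce deterministic byte streams for a
given input (no timestamps).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif import Motif, motif_to_pfm
from .records import BetaMatrix, CpGRecord
from .synthetic import GroundTruth
from .tfbs import TFMotif

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """FASTA as an ordered dict id -> uppercase sequence."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record ID {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# MEME minimal motif format (version 4)


def write_meme_motifs(motifs: list[TFMotif], path, nsites: int = 20) -> None:
    """Write PFMs in MEME minimal format with a uniform background line."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.tf_name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(m)} "
                f"nsites= {nsites} E= 0\n"
            )
            for row in m.pwm:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_meme_motifs(path, classes: dict[str, str] | None = None) -> list[TFMotif]:
    """Parse MEME minimal format; optional methyl-class annotation by name."""
    motifs: list[TFMotif] = []
    name = None
    rows: list[list[float]] = []
    expect = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if line.startswith("MOTIF"):
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"malformed MOTIF line {lineno}")
                name = parts[1]
            elif line.startswith("letter-probability matrix"):
                tokens = line.replace(":", " ").split()
                try:
                    expect = int(tokens[tokens.index("w=") + 1])
                except (ValueError, IndexError) as exc:
                    raise ValueError(f"malformed matrix header at line {lineno}") from exc
                rows = []
            elif name is not None and expect > 0 and line and line[0] in "0123456789.":
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"expected 4 frequencies at line {lineno}")
                rows.append(vals)
                if len(rows) == expect:
                    # renormalize against truncation in the text encoding
                    pwm = np.array(rows)
                    pwm = pwm / pwm.sum(axis=1, keepdims=True)
                    cls = (classes or {}).get(name, "unknown")
                    motifs.append(TFMotif(tf_name=name, pwm=pwm, methyl_class=cls))
                    name, rows, expect = None, [], 0
    return motifs


def discovered_motifs_to_tfmotifs(motifs: list[Motif]) -> list[TFMotif]:
    """Wrap discovered IUPAC motifs as PFMs named by their consensus."""
    return [TFMotif(tf_name=m.consensus, pwm=motif_to_pfm(m)) for m in motifs]


# ---------------------------------------------------------------------------
# TSV tables


def read_beta_tsv(path) -> BetaMatrix:
    """Beta matrix TSV: first column cpg_id, remaining columns = samples.

    Rows with any missing value are dropped (count logged via warning text
    in the returned object is unnecessary; callers can diff shapes).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    n_before = len(df)
    df = df.dropna()
    df.attrs["n_dropped_na"] = n_before - len(df)
    return BetaMatrix(values=df)


def write_beta_tsv(matrix: BetaMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="cpg_id", float_format="%.6g")


def read_idmc_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cpg_id", "direction"} <= set(df.columns):
        raise ValueError("iDMC TSV needs columns cpg_id and direction")
    return df


def write_idmc_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> pd.DataFrame:
    """Annotation TSV: cpg_id, gene_regions (';'-joined, may be empty), cgi_region."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.set_index("cpg_id")
    df["gene_regions"] = [
        tuple(t for t in cell.split(";") if t) for cell in df["gene_regions"]
    ]
    return df


def write_annotation_tsv(records: list[CpGRecord], path) -> None:
    rows = [
        (r.cpg_id, ";".join(r.gene_regions), r.cgi_region) for r in records
    ]
    pd.DataFrame(rows, columns=["cpg_id", "gene_regions", "cgi_region"]).to_csv(
        path, sep="\t", index=False
    )


def read_classes_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["tf_name"], df["methyl_class"]))


def write_classes_tsv(classes: dict[str, str], path) -> None:
    pd.DataFrame(
        sorted(classes.items()), columns=["tf_name", "methyl_class"]
    ).to_csv(path, sep="\t", index=False)


def read_targets_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"tf_name", "gene"} <= set(df.columns):
        raise ValueError("target TSV needs columns tf_name and gene")
    return df


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


def read_sample_labels_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return pd.Series(
        df["condition"].to_numpy(), index=df["sample"].to_numpy(), name="condition"
    )


def write_sample_labels_tsv(labels: pd.Series, path) -> None:
    pd.DataFrame(
        {"sample": labels.index, "condition": labels.to_numpy()}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Fixture directory


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        "planted_occurrences": {
            w: sorted([list(t) for t in occ])
            for w, occ in truth.planted_occurrences.items()
        },
        "true_stable": sorted(truth.true_stable),
        "true_unstable": sorted(truth.true_unstable),
        "true_de_genes": dict(sorted(truth.true_de_genes.items())),
        "tf_classes": dict(sorted(truth.tf_classes.items())),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth_json(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        planted_occurrences={
            w: {(c, int(o)) for c, o in occ}
            for w, occ in payload["planted_occurrences"].items()
        },
        true_stable=frozenset(payload["true_stable"]),
        true_unstable=frozenset(payload["true_unstable"]),
        true_de_genes=payload["true_de_genes"],
        tf_classes=payload["tf_classes"],
    )


def write_fixture_dir(fixture: dict, outdir) -> None:
    """Materialize a synthetic fixture (see synthetic.gen_fixture) as files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records: list[CpGRecord] = fixture["records"]
    write_fasta({r.cpg_id: r.sequence for r in records}, outdir / "flanks.fa")
    write_annotation_tsv(records, outdir / "annotation.tsv")
    write_beta_tsv(fixture["beta"], outdir / "beta.tsv")
    write_idmc_tsv(fixture["idmc"], outdir / "idmc.tsv")
    write_meme_motifs(fixture["tf_db"], outdir / "tf_db.meme")
    write_classes_tsv(
        {tf.tf_name: tf.methyl_class for tf in fixture["tf_db"]},
        outdir / "tf_classes.tsv",
    )
    fixture["targets"].to_csv(outdir / "tf_targets.tsv", sep="\t", index=False)
    write_expression_tsv(fixture["expression"], outdir / "expression.tsv")
    write_sample_labels_tsv(fixture["expression_labels"], outdir / "sample_labels.tsv")
    write_ground_truth_json(fixture["truth"], outdir / "ground_truth.json")
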