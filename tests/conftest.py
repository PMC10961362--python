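"""Shared fixtures: a hand-built mini content bundle and VCF writers."""

from __future__ import annotations

import textwrap
from pathlib import Path

import pytest

from pgxkit import model


BUNDLE_TSVS = {
    # GENEA: reference *1, *2{rsA1}, *3{rsA2}, *4{rsA1,rsA2} with activity values
    # GENEB: reference *38 (non-*1 wild type), *17{rsB1}
    "genes.tsv": """\
        gene\tchrom\tstart\tend\treference_allele_name\tploidy_model
        GENEA\tchr10\t1000000\t1005000\t*1\tautosomal
        GENEB\tchr11\t2000000\t2004000\t*38\tautosomal
        """,
    "variants.tsv": """\
        gene\trsid\tchrom\tpos\tref\talt
        GENEA\trsA1\tchr10\t1000100\tG\tA
        GENEA\trsA2\tchr10\t1000200\tC\tT
        GENEB\trsB1\tchr11\t2000100\tA\tG
        GENEB\trsB2\tchr11\t2000200\tT\tC
        """,
    "haplotypes.tsv": """\
        gene\tallele\trsids\tfunction\tactivity_value
        GENEA\t*1\t\tnormal\t1.0
        GENEA\t*2\trsA1\tdecreased\t0.5
        GENEA\t*3\trsA2\tno\t0.0
        GENEA\t*4\trsA1;rsA2\tno\t0.0
        GENEB\t*38\t\tnormal\t
        GENEB\t*17\trsB1\tincreased\t
        """,
    "frequencies.tsv": """\
        gene\tallele\tpopulation\tfrequency
        GENEA\t*1\tGLOBAL\t0.6
        GENEA\t*2\tGLOBAL\t0.25
        GENEA\t*3\tGLOBAL\t0.1
        GENEA\t*4\tGLOBAL\t0.03
        GENEA\t*5\tGLOBAL\t0.02
        GENEA\t*2\tEAS\t0.4
        GENEA\t*1\tEAS\t0.5
        GENEA\t*3\tEAS\t0.05
        GENEA\t*4\tEAS\t0.03
        GENEA\t*5\tEAS\t0.02
        GENEB\t*38\tGLOBAL\t0.8
        GENEB\t*17\tGLOBAL\t0.2
        """,
    "phenotypes.tsv": """\
        gene\tallele1\tallele2\tphenotype
        GENEA\t*1\t*1\tNormal Metabolizer
        GENEA\t*1\t*2\tNormal Metabolizer
        GENEA\t*1\t*3\tIntermediate Metabolizer
        GENEA\t*1\t*4\tIntermediate Metabolizer
        GENEA\t*1\t*5\tIntermediate Metabolizer
        GENEA\t*2\t*2\tIntermediate Metabolizer
        GENEA\t*2\t*3\tIntermediate Metabolizer
        GENEA\t*2\t*4\tIntermediate Metabolizer
        GENEA\t*2\t*5\tIntermediate Metabolizer
        GENEA\t*3\t*3\tPoor Metabolizer
        GENEA\t*3\t*4\tPoor Metabolizer
        GENEA\t*3\t*5\tPoor Metabolizer
        GENEA\t*4\t*4\tPoor Metabolizer
        GENEA\t*4\t*5\tPoor Metabolizer
        GENEA\t*5\t*5\tPoor Metabolizer
        GENEB\t*38\t*38\tNormal Metabolizer
        GENEB\t*17\t*38\tRapid Metabolizer
        GENEB\t*17\t*17\tUltrarapid Metabolizer
        """,
    "equivalences.tsv": """\
        gene\tfrom_allele\tto_allele
        GENEA\t*2\t*1
        """,
}


def write_mini_bundle(dir_path: Path, edits: dict[str, str] | None = None) -> Path:
    dir_path.mkdir(parents=True, exist_ok=True)
    files = dict(BUNDLE_TSVS)
    files.update(edits or {})
    for name, content in files.items():
        (dir_path / name).write_text(textwrap.dedent(content))
    return dir_path


@pytest.fixture
def mini_bundle_dir(tmp_path) -> Path:
    return write_mini_bundle(tmp_path / "bundle")


@pytest.fixture
def mini_bundle(mini_bundle_dir) -> model.ContentBundle:
    return model.load_bundle(mini_bundle_dir)


def write_vcf_text(path: Path, body: str, samples: list[str],
                   extra_format: str = "") -> Path:
    """Write a small VCF with the given data lines (tab-normalized)."""
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr10>\n"
        "##contig=<ID=chr11>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        + extra_format
        + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples) + "\n"
    )
    lines = [
        "\t".join(line.split()) for line in textwrap.dedent(body).strip().splitlines()
        if line.strip()
    ]
    path.write_text(header + ("\n".join(lines) + "\n" if lines else ""))
    return path
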