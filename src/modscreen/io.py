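"""Readers and writers for the pipeline's on-disk formats.

VCF (diploid homozygous calls mapped to 0/1), GFF3 (1-based inclusive
intervals), GMT gene sets, Newick rate trees (one file per clade, one tree
per gene with the gene id as the root label), and TSV tables.  Generated
files round-trip: reading a written file reproduces the in-memory object.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from modscreen.containers import GeneModel, GeneModelSet, GenotypePanel, RateTreeSet

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# VCF


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write the panel as a minimal VCF with homozygous diploid genotypes."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, sub in panel.variants.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.strain_ids)
            + "\n"
        )
        G = panel.genotypes
        for j, row in enumerate(panel.variants.itertuples(index=False)):
            calls = []
            for i in range(panel.n_strains):
                g = G[i, j]
                calls.append("./." if np.isnan(g) else ("1/1" if g == 1 else "0/0"))
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read a VCF of inbred lines into a 0/1 genotype panel.

    Homozygous ref/alt map to 0/1; heterozygous or unknown calls become
    missing (counted and logged); non-biallelic records are dropped.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    strain_ids = list(vcf.samples)
    rows = []
    geno_cols = []
    n_het = 0
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(v.gt_types)  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        col = np.full(len(gt), np.nan)
        col[gt == 0] = 0.0
        col[gt == 3] = 1.0
        n_het += int(np.sum(gt == 1))
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        rows.append({"chrom": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": v.ALT[0], "id": vid})
        geno_cols.append(col)
    vcf.close()
    if n_het:
        logger.info("treated %d heterozygous calls as missing", n_het)
    if n_multi:
        logger.info("dropped %d non-biallelic records", n_multi)
    if not rows:
        raise ParseError(f"{path}: no biallelic records")
    return GenotypePanel(
        strain_ids=strain_ids,
        variants=pd.DataFrame(rows),
        genotypes=np.column_stack(geno_cols),
    )


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(models: GeneModelSet, path: str | Path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/UTR features, 1-based inclusive)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            gid = g.gene_id
            fh.write(
                f"{g.chrom}\tmodscreen\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={gid}\n"
            )
            mid = f"{gid}.t1"
            fh.write(
                f"{g.chrom}\tmodscreen\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent={gid}\n"
            )
            for lo, hi in g.exons:
                fh.write(
                    f"{g.chrom}\tmodscreen\texon\t{lo}\t{hi}\t.\t{g.strand}\t.\tParent={mid}\n"
                )
            for k, (lo, hi) in enumerate(g.utrs):
                five = (k == 0) == (g.strand == "+")
                sotype = "five_prime_UTR" if five else "three_prime_UTR"
                fh.write(
                    f"{g.chrom}\tmodscreen\t{sotype}\t{lo}\t{hi}\t.\t{g.strand}\t.\tParent={mid}\n"
                )


_ATTR_RE = re.compile(r"(\w+)=([^;]+)")


def read_gff3(path: str | Path) -> GeneModelSet:
    """Read gene models from GFF3 (gene, exon and UTR features)."""
    path = Path(path)
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    order: list[str] = []
    with path.open("r", newline=None) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            attr = dict(_ATTR_RE.findall(attrs))
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise ParseError(f"{path}:{lineno}: gene feature without ID")
                genes[gid] = {
                    "chrom": chrom,
                    "start": start_i,
                    "end": end_i,
                    "strand": strand,
                    "exons": [],
                    "utrs": [],
                }
                order.append(gid)
            elif ftype == "mRNA":
                mrna_parent[attr.get("ID", "")] = attr.get("Parent", "")
            elif ftype in ("exon", "five_prime_UTR", "three_prime_UTR"):
                parent = attr.get("Parent", "")
                gid = mrna_parent.get(parent, parent)
                if gid not in genes:
                    raise ParseError(f"{path}:{lineno}: feature parent {parent!r} unknown")
                key = "exons" if ftype == "exon" else "utrs"
                genes[gid][key].append((start_i, end_i))
    return GeneModelSet(
        genes=[GeneModel(gene_id=gid, **genes[gid]) for gid in order]
    )


# ---------------------------------------------------------------------------
# GMT


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name in sets:
            fh.write("\t".join([name, "na", *sets[name]]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    path = Path(path)
    out: dict[str, list[str]] = {}
    with path.open("r", newline=None) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            out[parts[0]] = parts[2:]
    return out


# ---------------------------------------------------------------------------
# Newick rate trees


def write_rate_trees(trees: RateTreeSet, outdir: str | Path, prefix: str = "rates") -> list[Path]:
    """One Newick file per clade; one tree per gene, gene id as root label.

    Branch lengths are substituted into the clade's topology skeleton in
    string order, so a re-read reproduces each gene's vector exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for clade in trees.clade_ids:
        skeleton = trees.topologies.get(clade)
        if skeleton is None:
            raise ValueError(f"clade {clade} has no topology; cannot serialise")
        path = outdir / f"{prefix}_{clade}.nwk"
        with path.open("w") as fh:
            for gene in sorted(trees.branch_lengths[clade]):
                vec = trees.branch_lengths[clade][gene]
                vals = {f"b{i}": format(v, ".17g") for i, v in enumerate(vec)}
                newick = skeleton.format(**vals)
                assert newick.endswith(";")
                fh.write(newick[:-1] + gene + ";\n")
        paths.append(path)
    return paths


def _tree_branch_vector(tree: dendropy.Tree) -> np.ndarray:
    """Branch lengths of all non-root nodes in postorder = newick string order."""
    out = []
    for node in tree.postorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise ParseError("newick tree has a branch without a length")
        out.append(float(node.edge.length))
    return np.asarray(out)


def read_rate_trees(paths: dict[str, str | Path]) -> RateTreeSet:
    """Read per-clade Newick files (clade id -> path) into a RateTreeSet.

    Branch vectors are taken in newick string order (postorder over non-root
    nodes), matching the writer's convention.
    """
    clade_ids = sorted(paths)
    n_branches: dict[str, int] = {}
    branch_lengths: dict[str, dict[str, np.ndarray]] = {}
    topologies: dict[str, str] = {}
    for clade in clade_ids:
        tl = dendropy.TreeList.get(
            path=str(paths[clade]), schema="newick", preserve_underscores=True
        )
        vecs: dict[str, np.ndarray] = {}
        for tree in tl:
            gene = tree.seed_node.label
            if gene is None:
                raise ParseError(f"{paths[clade]}: tree without a gene id root label")
            vecs[gene] = _tree_branch_vector(tree)
        if not vecs:
            raise ParseError(f"{paths[clade]}: no trees")
        lens = {len(v) for v in vecs.values()}
        if len(lens) != 1:
            raise ParseError(f"{paths[clade]}: trees disagree on branch count")
        n_branches[clade] = lens.pop()
        branch_lengths[clade] = vecs
        topologies[clade] = _skeletonise(tl[0])
    return RateTreeSet(
        clade_ids=clade_ids,
        n_branches=n_branches,
        branch_lengths=branch_lengths,
        topologies=topologies,
    )


def _skeletonise(tree: dendropy.Tree) -> str:
    """Rebuild the ``{b<i>}`` placeholder skeleton from a parsed tree."""
    counter = [0]

    def render(node) -> str:
        if node.is_leaf():
            base = node.taxon.label.replace(" ", "_") if node.taxon else (node.label or "")
        else:
            base = "(" + ",".join(render(c) for c in node.child_nodes()) + ")"
        if node.parent_node is None:
            return base
        s = f"{base}:{{b{counter[0]}}}"
        counter[0] += 1
        return s

    # placeholder numbering must follow string order (postorder), not the
    # preorder in which render() recurses, so renumber afterwards
    raw = render(tree.seed_node) + ";"
    idx = [0]

    def renumber(m):
        s = f"{{b{idx[0]}}}"
        idx[0] += 1
        return s

    return re.sub(r"\{b\d+\}", renumber, raw)


# ---------------------------------------------------------------------------
# TSV


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_grm_tsv(K, path: str | Path) -> None:
    """Kinship matrix as a TSV with strain-id header and row labels."""
    df = pd.DataFrame(K.K, index=K.strain_ids, columns=K.strain_ids)
    df.to_csv(path, sep="\t", index_label="strain")


def read_grm_tsv(path: str | Path):
    from modscreen.containers import KinshipMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return KinshipMatrix(
        K=df.to_numpy(dtype=float), strain_ids=list(df.columns), p_variants_used=0
    )
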