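"""SNP matrices, taxon groupings and discrete trait tables.

The SNP container holds individuals x biallelic sites with genotype codes
{0, 1, 2} and -1 for missing; positions are 1-based within a locus. Native
serialisation is a TSV dialect (columns ``locus  pos  ref  alt`` followed
by one genotype column per individual, ``.`` for missing); VCF is read via
cyvcf2 when available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SNPMatrix", "GroupingConfig", "TraitTable"]

MISSING = -1


@dataclass
class SNPMatrix:
    individuals: list
    sites: pd.DataFrame  # columns: locus, pos, ref, alt
    genotypes: np.ndarray  # (n_sites, n_individuals), int8, -1 = missing

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.individuals)):
            raise ValueError(
                f"genotype shape {self.genotypes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.individuals)} individuals"
            )
        bad = ~np.isin(self.genotypes, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        for locus, sub in self.sites.groupby("locus", sort=False):
            p = sub["pos"].to_numpy()
            if not (np.diff(p) > 0).all():
                raise ValueError(
                    f"positions not strictly increasing within locus {locus!r}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset_sites(self, mask) -> "SNPMatrix":
        mask = np.asarray(mask)
        return SNPMatrix(
            individuals=list(self.individuals),
            sites=self.sites.loc[mask].reset_index(drop=True),
            genotypes=self.genotypes[mask],
        )

    def missing_fraction(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=1)

    # ------------------------------------------------------------------
    def to_tsv(self, path) -> None:
        df = self.sites.copy()
        g = self.genotypes.astype(object)
        g[g == MISSING] = "."
        for j, ind in enumerate(self.individuals):
            df[ind] = g[:, j]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SNPMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"locus": str})
        meta = ["locus", "pos", "ref", "alt"]
        inds = [c for c in df.columns if c not in meta]
        g = df[inds].replace(".", MISSING).to_numpy(dtype=np.int8)
        return cls(individuals=inds, sites=df[meta].copy(), genotypes=g)

    # ------------------------------------------------------------------
    def to_vcf(self, path) -> None:
        """Minimal single-sample-column-per-individual haploid/diploid VCF."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(map(str, self.individuals))
                + "\n"
            )
            code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
            for i, row in enumerate(self.sites.itertuples(index=False)):
                gts = "\t".join(code[int(x)] for x in self.genotypes[i])
                fh.write(
                    f"{row.locus}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "SNPMatrix":
        """Read a VCF; CHROM is taken as the locus ID; multiallelic sites kept
        only when biallelic after splitting is not attempted (dropped)."""
        try:
            from cyvcf2 import VCF
        except ImportError:  # pragma: no cover - plain-text fallback
            return cls._from_vcf_text(path)
        v = VCF(str(path))
        inds = list(v.samples)
        loci, pos, ref, alt, rows = [], [], [], [], []
        for rec in v:
            if len(rec.ALT) != 1:
                continue
            g = np.array(rec.gt_types, dtype=np.int8)  # 0 hom-ref,1 het,2 unk?,3 hom-alt
            # cyvcf2: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
            out = np.full(len(inds), MISSING, dtype=np.int8)
            out[g == 0] = 0
            out[g == 1] = 1
            out[g == 3] = 2
            loci.append(rec.CHROM)
            pos.append(rec.POS)
            ref.append(rec.REF)
            alt.append(rec.ALT[0])
            rows.append(out)
        sites = pd.DataFrame({"locus": loci, "pos": pos, "ref": ref, "alt": alt})
        g = np.vstack(rows) if rows else np.empty((0, len(inds)), dtype=np.int8)
        return cls(individuals=inds, sites=sites, genotypes=g)

    @classmethod
    def _from_vcf_text(cls, path) -> "SNPMatrix":
        code = {"0/0": 0, "0|0": 0, "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
                "1/1": 2, "1|1": 2, "0": 0, "1": 1}
        inds: list[str] = []
        loci, pos, ref, alt, rows = [], [], [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("##") or not line:
                    continue
                if line.startswith("#CHROM"):
                    inds = line.split("\t")[9:]
                    continue
                f = line.split("\t")
                if "," in f[4]:
                    continue
                gts = [x.split(":")[0] for x in f[9:]]
                rows.append([code.get(x, MISSING) for x in gts])
                loci.append(f[0])
                pos.append(int(f[1]))
                ref.append(f[3])
                alt.append(f[4])
        sites = pd.DataFrame({"locus": loci, "pos": pos, "ref": ref, "alt": alt})
        g = (
            np.array(rows, dtype=np.int8)
            if rows
            else np.empty((0, len(inds)), dtype=np.int8)
        )
        return cls(individuals=inds, sites=sites, genotypes=g)


# ----------------------------------------------------------------------
@dataclass
class GroupingConfig:
    """Four named taxon groups plus an outgroup, with an individual->taxon map.

    Groups must be disjoint and nonempty; the individual map defaults to the
    identity (one individual per taxon, as in the target study design).
    """

    groups: dict  # name -> list of taxa; expects keys P1..P4 for quartet tests
    outgroup: list
    individual_to_taxon: dict = field(default_factory=dict)

    def __post_init__(self):
        seen: dict = {}
        for name, members in self.groups.items():
            if not members:
                raise ValueError(f"group {name!r} is empty")
            for m in members:
                if m in seen:
                    raise ValueError(
                        f"taxon {m!r} in both {seen[m]!r} and {name!r}"
                    )
                seen[m] = name
        for m in self.outgroup:
            if m in seen:
                raise ValueError(f"outgroup taxon {m!r} also in group {seen[m]!r}")

    @property
    def quartet_groups(self) -> list:
        return [self.groups[k] for k in ("P1", "P2", "P3", "P4")]

    def all_taxa(self) -> list:
        out = []
        for members in self.groups.values():
            out.extend(members)
        out.extend(self.outgroup)
        return out

    def taxon_of(self, individual) -> str:
        return self.individual_to_taxon.get(individual, individual)

    # ------------------------------------------------------------------
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("individual\ttaxon\tgroup\n")
            for name, members in self.groups.items():
                for m in members:
                    for ind in self._individuals_of(m):
                        fh.write(f"{ind}\t{m}\t{name}\n")
            for m in self.outgroup:
                for ind in self._individuals_of(m):
                    fh.write(f"{ind}\t{m}\toutgroup\n")

    def _individuals_of(self, taxon):
        inds = [i for i, t in self.individual_to_taxon.items() if t == taxon]
        return inds or [taxon]

    @classmethod
    def from_tsv(cls, path) -> "GroupingConfig":
        df = pd.read_csv(path, sep="\t", dtype=str)
        groups: dict = {}
        outgroup: list = []
        ind_map: dict = {}
        for row in df.itertuples(index=False):
            ind_map[row.individual] = row.taxon
            target = outgroup if row.group == "outgroup" else groups.setdefault(
                row.group, []
            )
            if row.taxon not in target:
                target.append(row.taxon)
        ind_map = {i: t for i, t in ind_map.items() if i != t}
        return cls(groups=groups, outgroup=outgroup, individual_to_taxon=ind_map)


# ----------------------------------------------------------------------
@dataclass
class TraitTable:
    """Taxon -> discrete state, one column per trait."""

    data: pd.DataFrame  # index: taxon, columns: trait names

    TRAITS = ("longevity", "fruit", "environment")
    STATES = {
        "longevity": ("semelparous", "iteroparous"),
        "fruit": ("homocarpic", "heterocarpic"),
        "environment": ("predictable", "unpredictable"),
    }

    def states(self, trait: str) -> dict:
        col = self.data[trait].dropna()
        return col.to_dict()

    def check_coverage(self, taxa, trait: str) -> list:
        """Taxa lacking a state for `trait`."""
        have = set(self.data[trait].dropna().index)
        return [t for t in taxa if t not in have]

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="taxon")

    @classmethod
    def from_tsv(cls, path) -> "TraitTable":
        return cls(pd.read_csv(path, sep="\t", index_col="taxon", dtype=str))
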