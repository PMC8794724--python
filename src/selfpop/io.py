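"""Readers, writers and filtering for microsatellite genotype and phenotype tables.

The central container is :class:`GenotypeMatrix`: a rectangular table of diploid
allele-pair calls (integer allele labels, typically fragment sizes) for two or
more temporal samples of the same population.  Missing calls are encoded as the
pair ``(0, 0)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = (0, 0)

PHENO_COLUMNS = ("plant", "family", "year", "treatment", "block", "flowering_time")


class ParseError(ValueError):
    """Malformed input file."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid genotype calls with temporal sample labels.

    calls[i, l] is the unordered allele pair of individual ``i`` at locus ``l``,
    stored sorted; ``(0, 0)`` marks a missing call.
    """

    individuals: list[str]
    years: dict[str, str]
    loci: list[str]
    calls: np.ndarray  # (n_ind, n_loci, 2) int

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=int)
        if self.calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError("calls shape does not match individuals x loci")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus names")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        missing_year = [i for i in self.individuals if i not in self.years]
        if missing_year:
            raise ValueError(f"individuals without year label: {missing_year[:5]}")
        # normalize: unordered pairs stored sorted, partial missing not allowed
        partial = (self.calls == 0).sum(axis=2) == 1
        if partial.any():
            raise ValueError("half-missing call (one allele 0): encode both as 0")
        if (self.calls < 0).any():
            raise ValueError("allele labels must be positive integers (0 = missing)")
        self.calls = np.sort(self.calls, axis=2)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def year_labels(self) -> list[str]:
        seen: list[str] = []
        for ind in self.individuals:
            y = self.years[ind]
            if y not in seen:
                seen.append(y)
        return seen

    @property
    def year_array(self) -> np.ndarray:
        return np.array([self.years[i] for i in self.individuals])

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_ind, n_loci); True where the call is missing."""
        return (self.calls == 0).all(axis=2)

    def subset(self, ind_idx=None, loci_idx=None) -> "GenotypeMatrix":
        ind_idx = np.arange(self.n_individuals) if ind_idx is None else np.asarray(ind_idx, dtype=int)
        loci_idx = np.arange(self.n_loci) if loci_idx is None else np.asarray(loci_idx, dtype=int)
        inds = [self.individuals[i] for i in ind_idx]
        return GenotypeMatrix(
            individuals=inds,
            years={i: self.years[i] for i in inds},
            loci=[self.loci[j] for j in loci_idx],
            calls=self.calls[np.ix_(ind_idx, loci_idx)],
        )

    def for_year(self, year: str) -> "GenotypeMatrix":
        idx = [i for i, ind in enumerate(self.individuals) if self.years[ind] == str(year)]
        if not idx:
            raise ValueError(f"no individuals for year {year!r}")
        return self.subset(ind_idx=idx)

    def allele_counts(self, locus: int, year: str | None = None) -> dict[int, int]:
        """Gene-copy counts per allele at one locus (optionally one year)."""
        calls = self.calls[:, locus, :]
        if year is not None:
            calls = calls[self.year_array == str(year)]
        alleles = calls.ravel()
        alleles = alleles[alleles > 0]
        vals, counts = np.unique(alleles, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclass
class FilterReport:
    loci_dropped: dict[str, str] = field(default_factory=dict)  # locus -> reason
    individuals_dropped: list[str] = field(default_factory=list)
    n_individuals_kept: int = 0
    n_loci_kept: int = 0
    per_year_kept: dict[str, int] = field(default_factory=dict)
    order: tuple[str, ...] = ("loci_missingness", "individual_missingness", "monomorphic")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, default=list, sort_keys=True, indent=2)


def filter_genotypes(
    gm: GenotypeMatrix, max_missing: float = 0.10, drop_monomorphic: bool = True
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the study's preprocessing: drop loci then individuals with a
    missing-data fraction strictly above ``max_missing``, then monomorphic loci.

    The ">10%" rule is strict: exactly 10% missing is kept.
    """
    if gm.n_individuals == 0 or gm.n_loci == 0:
        raise ValueError("empty genotype matrix")
    report = FilterReport()
    miss = gm.missing_mask()

    locus_frac = miss.mean(axis=0)
    keep_loci = locus_frac <= max_missing
    for j in np.flatnonzero(~keep_loci):
        report.loci_dropped[gm.loci[j]] = "missingness"

    ind_frac = miss[:, keep_loci].mean(axis=1) if keep_loci.any() else np.ones(gm.n_individuals)
    keep_ind = ind_frac <= max_missing
    report.individuals_dropped = [gm.individuals[i] for i in np.flatnonzero(~keep_ind)]

    out = gm.subset(np.flatnonzero(keep_ind), np.flatnonzero(keep_loci))

    if drop_monomorphic:
        poly = []
        for j in range(out.n_loci):
            if len(out.allele_counts(j)) >= 2:
                poly.append(j)
            else:
                report.loci_dropped[out.loci[j]] = "monomorphic"
        out = out.subset(loci_idx=poly)

    if out.n_loci == 0:
        raise ValueError("no polymorphic loci survive filtering")
    report.n_individuals_kept = out.n_individuals
    report.n_loci_kept = out.n_loci
    years = out.year_array
    report.per_year_kept = {y: int((years == y).sum()) for y in out.year_labels}
    return out, report


# ---------------------------------------------------------------------------
# Genepop 4.x dialect
# ---------------------------------------------------------------------------

def read_genepop(path, pop_years: list[str] | None = None) -> GenotypeMatrix:
    """Read a Genepop 4.x file with 2- or 3-digit allele encoding.

    POP blocks are mapped to year labels.  Labels are taken, in order of
    precedence, from ``pop_years``, from a ``years=y1,y2`` token in the title
    line, or default to ``pop1..popN``.  Allele code 0 decodes to missing.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    title = lines[0]
    if pop_years is None and "years=" in title:
        pop_years = title.split("years=")[1].split()[0].split(",")

    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        chunk = [s.strip() for s in lines[i].split(",") if s.strip()]
        if not chunk:
            raise ParseError(f"{path}: line {i + 1}: blank line before first POP")
        loci.extend(chunk)
        i += 1
    if i == len(lines):
        raise ParseError(f"{path}: no POP line found")

    individuals: list[str] = []
    years: dict[str, str] = {}
    rows: list[np.ndarray] = []
    digits: int | None = None
    pop = -1
    for lineno in range(i, len(lines)):
        line = lines[lineno]
        if not line.strip():
            continue
        if line.strip().upper() == "POP":
            pop += 1
            continue
        if "," not in line:
            raise ParseError(f"{path}: line {lineno + 1}: expected 'id , genotypes'")
        ind_id, _, geno = line.partition(",")
        ind_id = ind_id.strip()
        fields = geno.split()
        if len(fields) != len(loci):
            raise ParseError(
                f"{path}: line {lineno + 1}: {len(fields)} genotype fields for {len(loci)} loci"
            )
        calls = np.zeros((len(loci), 2), dtype=int)
        for j, tok in enumerate(fields):
            if not tok.isdigit() or len(tok) % 2:
                raise ParseError(f"{path}: line {lineno + 1}: bad genotype token {tok!r}")
            w = len(tok) // 2
            if w not in (2, 3):
                raise ParseError(f"{path}: line {lineno + 1}: allele width {w} not in (2, 3)")
            if digits is None:
                digits = w
            elif w != digits:
                raise ParseError(f"{path}: line {lineno + 1}: inconsistent digit width")
            a, b = int(tok[:w]), int(tok[w:])
            if (a == 0) != (b == 0):
                a = b = 0  # half-missing treated as missing
            calls[j] = (a, b)
        if ind_id in years:
            raise ParseError(f"{path}: line {lineno + 1}: duplicate individual id {ind_id!r}")
        label = (
            pop_years[pop]
            if pop_years is not None and pop < len(pop_years)
            else f"pop{pop + 1}"
        )
        individuals.append(ind_id)
        years[ind_id] = str(label)
        rows.append(calls)
    if not rows:
        raise ParseError(f"{path}: no individuals")
    return GenotypeMatrix(individuals, years, loci, np.stack(rows))


def write_genepop(gm: GenotypeMatrix, path, digits: int = 3, title: str | None = None) -> None:
    labels = gm.year_labels
    if title is None:
        title = "selfpop export years=" + ",".join(labels)
    fmt = f"{{:0{digits}d}}"
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in gm.loci:
            fh.write(locus + "\n")
        years = gm.year_array
        for label in labels:
            fh.write("POP\n")
            for i in np.flatnonzero(years == label):
                toks = [
                    fmt.format(a) + fmt.format(b) for a, b in gm.calls[i]
                ]
                fh.write(f"{gm.individuals[i]} , " + " ".join(toks) + "\n")


# ---------------------------------------------------------------------------
# long-format genotype CSV dialect: ind,year,locus,allele1,allele2
# ---------------------------------------------------------------------------

def read_genotype_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype={"ind": str, "year": str, "locus": str})
    required = {"ind", "year", "locus", "allele1", "allele2"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    df["allele1"] = df["allele1"].fillna(0).astype(int)
    df["allele2"] = df["allele2"].fillna(0).astype(int)
    individuals = list(dict.fromkeys(df["ind"]))
    loci = list(dict.fromkeys(df["locus"]))
    years = {}
    for ind, sub in df.groupby("ind", sort=False):
        y = sub["year"].unique()
        if len(y) > 1:
            raise ParseError(f"{path}: individual {ind!r} has several year labels")
        years[ind] = y[0]
    calls = np.zeros((len(individuals), len(loci), 2), dtype=int)
    ind_pos = {v: k for k, v in enumerate(individuals)}
    loc_pos = {v: k for k, v in enumerate(loci)}
    for row in df.itertuples(index=False):
        a, b = int(row.allele1), int(row.allele2)
        if (a == 0) != (b == 0):
            a = b = 0
        calls[ind_pos[row.ind], loc_pos[row.locus]] = (a, b)
    return GenotypeMatrix(individuals, years, loci, calls)


def write_genotype_csv(gm: GenotypeMatrix, path) -> None:
    recs = []
    for i, ind in enumerate(gm.individuals):
        for j, locus in enumerate(gm.loci):
            a, b = gm.calls[i, j]
            recs.append((ind, gm.years[ind], locus, a, b))
    pd.DataFrame(recs, columns=["ind", "year", "locus", "allele1", "allele2"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Plant-level phenotypes from the common-garden (greenhouse) design.

    Columns: plant, family, year, treatment, block, flowering_time (degree.days),
    optionally seeds; categorical columns are stored as strings.
    """

    data: pd.DataFrame
    n_excluded: int = 0

    def __post_init__(self) -> None:
        df = self.data
        for col in PHENO_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"phenotype table missing column {col!r}")
        if df["plant"].duplicated().any():
            dup = df.loc[df["plant"].duplicated(), "plant"].iloc[0]
            raise ValueError(f"duplicated plant id {dup!r}")
        fam_years = df.groupby("family")["year"].nunique()
        if (fam_years > 1).any():
            raise ValueError("a family maps to more than one sampling year")
        ft = pd.to_numeric(df["flowering_time"], errors="raise")
        if (ft.dropna() < 0).any():
            raise ValueError("negative flowering_time")
        if "seeds" in df.columns and df["seeds"].notna().any():
            seeds = pd.to_numeric(df["seeds"], errors="raise")
            if (seeds.dropna() < 0).any():
                raise ValueError("negative seed count")

    @property
    def has_seeds(self) -> bool:
        return "seeds" in self.data.columns and self.data["seeds"].notna().any()

    def cell(self, year=None, treatment=None) -> pd.DataFrame:
        df = self.data
        if year is not None:
            df = df[df["year"] == str(year)]
        if treatment is not None:
            df = df[df["treatment"] == str(treatment)]
        return df


def read_phenotypes(path) -> PhenotypeTable:
    """Read the plant-level phenotype CSV; rows flagged not alive are dropped
    (and counted), mirroring the removal of sick plants from the experiment."""
    df = pd.read_csv(path)
    for col in PHENO_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing mandatory column {col!r}")
    for col in ("plant", "family", "year", "treatment", "block"):
        df[col] = df[col].astype(str)
    try:
        df["flowering_time"] = pd.to_numeric(df["flowering_time"])
        if "seeds" in df.columns:
            df["seeds"] = pd.to_numeric(df["seeds"])
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: non-numeric trait value ({exc})") from exc
    n_excluded = 0
    if "alive" in df.columns:
        alive = df["alive"].astype(str).str.lower().isin(("1", "true", "yes", "t"))
        n_excluded = int((~alive).sum())
        df = df[alive].drop(columns=["alive"]).reset_index(drop=True)
    return PhenotypeTable(df, n_excluded=n_excluded)


def read_temperatures(path) -> pd.Series:
    """Daily mean temperature series from a CSV with columns day,temp."""
    df = pd.read_csv(path)
    if not {"day", "temp"}.issubset(df.columns):
        raise ParseError(f"{path}: need columns day,temp")
    s = pd.Series(df["temp"].to_numpy(float), index=df["day"].astype(int).to_numpy())
    if s.index.duplicated().any():
        raise ParseError(f"{path}: duplicated days")
    return s.sort_index()
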