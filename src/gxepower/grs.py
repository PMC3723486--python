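"""Unweighted 12-SNP genetic risk score (GRS) construction.

The GRS counts BMI-raising alleles across twelve established obesity
susceptibility loci, so a complete-data participant scores an integer in
[0, 24].  Construction follows the cohort-analysis conventions for this
panel: dosages coded 0/1/2 on the risk allele, per-locus QC on call rate
(>= 95%) and Hardy-Weinberg equilibrium (chi-square, P > 0.001), and
expected-dosage imputation for participants missing four or fewer
genotypes (participants missing more are excluded).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: The 12-locus obesity panel, in canonical column order: (rsid, nearest gene).
SNP_PANEL: tuple[tuple[str, str], ...] = (
    ("rs1121980", "FTO"),
    ("rs7498665", "SH2B1"),
    ("rs10913469", "SEC16B"),
    ("rs10838738", "MTCH2"),
    ("rs17782313", "MC4R"),
    ("rs3101336", "NEGR1"),
    ("rs6548238", "TMEM18"),
    ("rs10938397", "GNPDA2"),
    ("rs925946", "BDNF"),
    ("rs368794", "KCTD15"),
    ("rs7647305", "ETV5"),
    ("rs7132908", "FAIM2"),
)

PANEL_RSIDS: tuple[str, ...] = tuple(s for s, _ in SNP_PANEL)
PANEL_GENES: tuple[str, ...] = tuple(g for _, g in SNP_PANEL)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _revcomp(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(allele.upper()))


@dataclass(frozen=True)
class RiskLocus:
    """One panel locus: SNP id, the BMI-raising (risk) allele, and the
    non-risk allele; ``proxy`` optionally names an LD proxy genotyped in
    place of the index SNP."""

    snp: str
    risk_allele: str
    other_allele: str | None = None
    gene: str | None = None
    proxy: str | None = None


@dataclass(frozen=True)
class RiskAlleleMap:
    """Risk-allele orientation for the 12-locus panel.

    Exactly twelve loci with unique SNP ids. Real analyses must supply
    alleles from the source genotyping; :meth:`default_panel` uses a
    synthetic A(risk)/G(other) convention suitable only for simulated
    dosage data, where allele identity is arbitrary.
    """

    loci: tuple[RiskLocus, ...]

    def __post_init__(self) -> None:
        ids = [l.snp for l in self.loci]
        if len(ids) != 12:
            raise ValueError(f"risk-allele map must list exactly 12 loci, got {len(ids)}")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids in risk-allele map")

    def __getitem__(self, snp: str) -> RiskLocus:
        for locus in self.loci:
            if locus.snp == snp or locus.proxy == snp:
                return locus
        raise KeyError(snp)

    def __contains__(self, snp: str) -> bool:
        try:
            self[snp]
        except KeyError:
            return False
        return True

    @classmethod
    def default_panel(cls) -> "RiskAlleleMap":
        return cls(tuple(RiskLocus(snp=s, risk_allele="A", other_allele="G", gene=g)
                         for s, g in SNP_PANEL))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RiskAlleleMap":
        """Build from a table with columns snp, risk_allele and optionally
        other_allele, gene, proxy."""
        loci = []
        for _, row in frame.iterrows():
            loci.append(RiskLocus(
                snp=str(row["snp"]),
                risk_allele=str(row["risk_allele"]).upper(),
                other_allele=(str(row["other_allele"]).upper()
                              if "other_allele" in frame.columns and pd.notna(row.get("other_allele")) else None),
                gene=str(row["gene"]) if "gene" in frame.columns and pd.notna(row.get("gene")) else None,
                proxy=str(row["proxy"]) if "proxy" in frame.columns and pd.notna(row.get("proxy")) else None,
            ))
        return cls(tuple(loci))


@dataclass
class GenotypeMatrix:
    """Participants x loci dosage matrix.

    ``dosages`` holds floats restricted to {0, 1, 2, NaN}; NaN marks a
    missing genotype (distinct from dosage 0).  ``coded_alleles`` records,
    per locus, which allele the dosage currently counts; ``None`` means
    orientation is unknown/already risk-aligned.
    """

    dosages: pd.DataFrame
    coded_alleles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = self.dosages.columns[np.argmax(~ok.all(axis=0))]
            raise ValueError(f"dosages must be 0/1/2 or missing; offending locus {bad!r}")

    @property
    def loci(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_participants(self) -> int:
        return len(self.dosages)

    def call_rate(self) -> pd.Series:
        return 1.0 - self.dosages.isna().mean(axis=0)

    def genotype_counts(self) -> pd.DataFrame:
        """Per-locus (hom_other, het, hom_counted) counts among called genotypes."""
        out = {}
        for locus in self.dosages.columns:
            col = self.dosages[locus]
            out[locus] = [(col == 0).sum(), (col == 1).sum(), (col == 2).sum()]
        return pd.DataFrame(out, index=["hom_other", "het", "hom_counted"]).T

    def allele_freq(self) -> pd.Series:
        """Frequency of the counted allele among non-missing genotypes."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.copy(), dict(self.coded_alleles))


def align_risk_alleles(geno: GenotypeMatrix, amap: RiskAlleleMap) -> GenotypeMatrix:
    """Orient dosages so that each counts the BMI-raising allele.

    Loci coded on the non-risk allele (directly or via strand complement)
    are flipped d -> 2 - d; flips are logged.  Strand-ambiguous A/T and
    C/G loci without resolvable orientation trigger a warning and are kept
    as coded (the documented convention).
    """
    out = geno.copy()
    for locus in out.loci:
        if locus not in amap:
            raise KeyError(f"locus {locus!r} absent from the risk-allele map")
        entry = amap[locus]
        coded = out.coded_alleles.get(locus)
        if coded is None:
            continue  # orientation unknown: assume already risk-aligned
        coded = coded.upper()
        risk, other = entry.risk_allele, entry.other_allele
        ambiguous = other is not None and {risk, other} in ({"A", "T"}, {"C", "G"})
        if ambiguous and coded not in (risk, other):
            warnings.warn(
                f"{locus}: ambiguous A/T or C/G orientation; keeping dosages as coded",
                stacklevel=2,
            )
            continue
        if coded == risk or coded == _revcomp(risk):
            flip = False
        elif (other is not None and (coded == other or coded == _revcomp(other))):
            flip = True
        else:
            raise ValueError(
                f"{locus}: coded allele {coded!r} matches neither risk ({risk!r}) "
                f"nor other ({other!r}) allele"
            )
        if flip:
            out.dosages[locus] = 2.0 - out.dosages[locus]
            out.coded_alleles[locus] = risk
            logger.info("flipped %s to count risk allele %s", locus, risk)
    return out


def hwe_chisq(n_hom_other: int, n_het: int, n_hom_counted: int) -> tuple[float, float]:
    """1-df chi-square test of Hardy-Weinberg proportions on genotype counts.

    Returns (chi2, p).  A monomorphic locus has no HWE information and is
    reported as chi2=0, p=1.
    """
    n = n_hom_other + n_het + n_hom_counted
    if n == 0:
        return 0.0, 1.0
    p = (2 * n_hom_counted + n_het) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    expected = np.array([q * q, 2 * p * q, p * p]) * n
    observed = np.array([n_hom_other, n_het, n_hom_counted], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def qc_variants(
    geno: GenotypeMatrix,
    min_call_rate: float = 0.95,
    hwe_alpha: float = 0.001,
) -> pd.DataFrame:
    """Per-locus QC report: call rate, counted-allele frequency, HWE test.

    Failing loci are flagged (``pass_call_rate`` / ``pass_hwe``) but never
    dropped — exclusion is a sensitivity analysis, not a default.
    Monomorphic loci get HWE p = 1 with a note.
    """
    counts = geno.genotype_counts()
    call = geno.call_rate()
    freq = geno.allele_freq()
    rows = []
    for locus in geno.loci:
        n0, n1, n2 = counts.loc[locus]
        chi2, p = hwe_chisq(int(n0), int(n1), int(n2))
        mono = (n1 == 0) and (n0 == 0 or n2 == 0)
        rows.append({
            "locus": locus,
            "call_rate": call[locus],
            "freq_counted": freq[locus],
            "n_hom_other": int(n0),
            "n_het": int(n1),
            "n_hom_counted": int(n2),
            "hwe_chi2": chi2,
            "hwe_p": p,
            "pass_call_rate": bool(call[locus] >= min_call_rate),
            "pass_hwe": bool(p > hwe_alpha),
            "note": "monomorphic" if mono else "",
        })
    report = pd.DataFrame(rows).set_index("locus")
    n_fail = int((~report["pass_call_rate"]).sum() + (~report["pass_hwe"]).sum())
    if n_fail:
        warnings.warn(f"{n_fail} QC flag(s) raised; see report", stacklevel=2)
    return report


@dataclass
class GRSResult:
    """Per-participant GRS after imputation.

    ``grs`` is NaN for excluded participants (more than ``max_missing``
    missing genotypes); non-excluded values lie in [0, 2 * n_loci].
    """

    grs: pd.Series
    n_missing_loci: pd.Series
    excluded: pd.Series
    n_imputed_entries: int

    def __post_init__(self) -> None:
        ok = self.grs[~self.excluded]
        upper = 2 * 12
        if len(ok) and ((ok < 0) | (ok > upper)).any():
            raise ValueError("GRS out of [0, 24] for a non-excluded participant")


def compute_grs(geno: GenotypeMatrix, max_missing: int = 4) -> GRSResult:
    """Sum risk-allele dosages into the GRS, imputing sparse missingness.

    A missing genotype is replaced by its expected dosage, 2 x the
    risk-allele frequency among participants called at that locus, for
    participants with at most ``max_missing`` missing loci; participants
    missing more are excluded (GRS = NaN, flagged).

    Raises if a locus is missing in every participant (no frequency to
    impute from).
    """
    dos = geno.dosages
    all_missing = dos.isna().all(axis=0)
    if all_missing.any():
        locus = all_missing.idxmax()
        raise ValueError(f"locus {locus!r} missing in all participants; cannot impute")
    n_missing = dos.isna().sum(axis=1)
    excluded = n_missing > max_missing
    expected = 2.0 * geno.allele_freq()  # per-locus expected dosage
    filled = dos.fillna(expected)
    grs = filled.sum(axis=1).astype(float)
    grs[excluded] = np.nan
    n_imputed = int(dos.loc[~excluded].isna().sum().sum())
    if excluded.any():
        logger.info("excluded %d participant(s) with > %d missing genotypes",
                    int(excluded.sum()), max_missing)
    return GRSResult(grs=grs, n_missing_loci=n_missing, excluded=excluded,
                     n_imputed_entries=n_imputed)


def dichotomize_grs(grs, cut: float = 11.0) -> np.ndarray:
    """Binary GRS indicator: 1 where GRS > cut, else 0.

    ``cut=11`` reproduces the >11 vs <=11 allele split used for stratified
    description; power scenarios cut at the GRS distribution mean instead.
    NaN inputs propagate as NaN.
    """
    arr = np.asarray(grs, dtype=float)
    out = (arr > cut).astype(float)
    out[np.isnan(arr)] = np.nan
    return out
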