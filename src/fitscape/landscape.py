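"""Combinatorial genotype->fitness landscapes.

A landscape is defined over an ordered set of n amino-acid substitutions
(at most one alternative allele per residue position). A genotype is any
subset of those substitutions; the canonical string form joins the
substitutions in ascending position order with ``+`` (``S41Y+R225V``), with
``WT`` denoting the empty genotype. Fitness is the fold-improvement in EC50
conferred relative to wild type, so the wild type sits at 1.0 by
definition. A complete landscape holds all 2^n genotypes.

Internally genotypes are bitmasks over the ordered substitution list
(lowest bit = lowest residue position), which keeps lattice operations on
the 2^n subsets cheap.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .library_design import AMINO_ACIDS, LibraryDesign, side_chain_category, SIDE_CHAIN_CATEGORIES

__all__ = [
    "Substitution",
    "FitnessMeasurement",
    "FitnessLandscape",
    "read_landscape",
    "write_landscape",
    "fold_improvement",
    "fold_from_replicates",
    "partition_summary",
    "category_profile",
    "PartitionSummary",
]

_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")

WT_TOKEN = "WT"


@dataclass(frozen=True, order=True)
class Substitution:
    """A single amino-acid substitution, e.g. S41Y."""

    position: int
    wild_type: str
    mutant: str

    def __post_init__(self) -> None:
        if self.wild_type not in AMINO_ACIDS or self.mutant not in AMINO_ACIDS:
            raise ValueError(f"non-standard residue in {self.wild_type}{self.position}{self.mutant}")
        if self.wild_type == self.mutant:
            raise ValueError(f"substitution {self}: wild-type and mutant residues are identical")
        if self.position < 1:
            raise ValueError(f"substitution {self}: position must be 1-based positive")

    @classmethod
    def parse(cls, token: str) -> "Substitution":
        m = _SUB_RE.match(token.strip().upper())
        if not m:
            raise ValueError(f"cannot parse substitution token {token!r} (expected e.g. 'S41Y')")
        wt, pos, mut = m.groups()
        return cls(position=int(pos), wild_type=wt, mutant=mut)

    def __str__(self) -> str:
        return f"{self.wild_type}{self.position}{self.mutant}"


def parse_genotype(token: str) -> tuple[Substitution, ...]:
    """Parse a '+'-joined genotype string to position-sorted substitutions.

    ``""`` and ``"WT"`` both denote the wild type. Duplicate positions are
    rejected (a landscape carries one alternative allele per position).
    """
    token = token.strip()
    if token in ("", WT_TOKEN):
        return ()
    subs = sorted(Substitution.parse(t) for t in token.split("+"))
    positions = [s.position for s in subs]
    if len(set(positions)) != len(positions):
        raise ValueError(f"genotype {token!r} has duplicate residue positions")
    return tuple(subs)


def format_genotype(subs: Sequence[Substitution]) -> str:
    if not subs:
        return WT_TOKEN
    return "+".join(str(s) for s in sorted(subs))


@dataclass(frozen=True)
class FitnessMeasurement:
    """Fold-improvement in EC50 over wild type: mean, SD, replicate count.

    ``replicates`` optionally carries per-replicate fold values; if present
    they must be consistent with mean/sd/n (sample SD, ddof=1).
    """

    mean: float
    sd: float = 0.0
    n: int = 1
    replicates: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not (self.mean > 0):
            raise ValueError(f"fitness mean must be > 0, got {self.mean}")
        if self.sd < 0:
            raise ValueError(f"fitness sd must be >= 0, got {self.sd}")
        if self.n < 1:
            raise ValueError(f"replicate count must be >= 1, got {self.n}")
        if self.replicates is not None:
            reps = tuple(float(r) for r in self.replicates)
            object.__setattr__(self, "replicates", reps)
            if len(reps) != self.n:
                raise ValueError(f"n={self.n} but {len(reps)} replicates supplied")
            if not math.isclose(float(np.mean(reps)), self.mean, rel_tol=1e-6, abs_tol=1e-9):
                raise ValueError("replicates inconsistent with stated mean")
            sd = float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0
            if not math.isclose(sd, self.sd, rel_tol=1e-6, abs_tol=1e-9):
                raise ValueError("replicates inconsistent with stated sd")

    @classmethod
    def from_replicates(cls, values: Iterable[float]) -> "FitnessMeasurement":
        vals = tuple(float(v) for v in values)
        if not vals:
            raise ValueError("at least one replicate required")
        return cls(
            mean=float(np.mean(vals)),
            sd=float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            n=len(vals),
            replicates=vals,
        )


class FitnessLandscape:
    """Map from genotype (subset of n substitutions) to fitness measurement.

    The wild type (empty genotype) is always present; if absent from the
    input it is inserted at its defining value of 1.0.
    """

    def __init__(
        self,
        substitutions: Sequence[Substitution],
        measurements: Mapping[int, FitnessMeasurement] | Mapping[str, FitnessMeasurement],
        name: str = "",
    ) -> None:
        subs = tuple(sorted(substitutions))
        positions = [s.position for s in subs]
        if len(set(positions)) != len(positions):
            raise ValueError("substitution list has duplicate residue positions")
        self.name = name
        self.substitutions = subs
        self._index = {s: i for i, s in enumerate(subs)}
        data: dict[int, FitnessMeasurement] = {}
        for key, meas in measurements.items():
            mask = key if isinstance(key, int) else self.mask_of(key)
            if mask in data:
                raise ValueError(f"duplicate genotype {self.genotype_string(mask)!r}")
            data[mask] = meas
        data.setdefault(0, FitnessMeasurement(mean=1.0, sd=0.0, n=1))
        self._data = data

    # -- genotype encoding ------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.substitutions)

    def mask_of(self, genotype: str | Sequence[Substitution]) -> int:
        subs = parse_genotype(genotype) if isinstance(genotype, str) else tuple(genotype)
        mask = 0
        for s in subs:
            try:
                mask |= 1 << self._index[s]
            except KeyError:
                raise KeyError(f"substitution {s} is not part of landscape {self.name!r}") from None
        return mask

    def genotype_string(self, mask: int) -> str:
        return format_genotype([s for i, s in enumerate(self.substitutions) if mask >> i & 1])

    def genotype_bits(self, mask: int) -> str:
        """Canonical bitstring, leftmost bit = lowest residue position."""
        return "".join("1" if mask >> i & 1 else "0" for i in range(self.n))

    # -- access -----------------------------------------------------------

    def __contains__(self, genotype: str | int) -> bool:
        mask = genotype if isinstance(genotype, int) else self.mask_of(genotype)
        return mask in self._data

    def measurement(self, genotype: str | int) -> FitnessMeasurement:
        mask = genotype if isinstance(genotype, int) else self.mask_of(genotype)
        try:
            return self._data[mask]
        except KeyError:
            raise KeyError(
                f"genotype {self.genotype_string(mask)!r} missing from landscape {self.name!r}"
            ) from None

    def mean(self, genotype: str | int) -> float:
        return self.measurement(genotype).mean

    @property
    def masks(self) -> list[int]:
        return sorted(self._data)

    @property
    def is_complete(self) -> bool:
        return len(self._data) == 2**self.n

    def missing_genotypes(self) -> list[str]:
        return [
            self.genotype_string(m) for m in range(2**self.n) if m not in self._data
        ]

    def require_complete(self, allow_incomplete: bool = False) -> bool:
        """Enforce (or warn about) completeness for lattice-wide operations."""
        if self.is_complete:
            return True
        missing = self.missing_genotypes()
        msg = (
            f"landscape {self.name!r} is incomplete: {len(missing)} of {2**self.n} "
            f"genotypes missing (first: {missing[:3]})"
        )
        if allow_incomplete:
            warnings.warn(msg + "; affected paths will be skipped", stacklevel=3)
            return False
        raise ValueError(msg)

    # -- lattice enumeration ----------------------------------------------

    def enumerate_intermediates(self) -> list[str]:
        """Genotypes strictly between wild type and the full variant.

        There are 2^n - 2 of them; ordering is by substitution count then
        canonical string, so the listing is deterministic.
        """
        full = 2**self.n - 1
        inter = [m for m in range(1, full)]
        inter.sort(key=lambda m: (bin(m).count("1"), self.genotype_string(m)))
        return [self.genotype_string(m) for m in inter]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mask in sorted(self._data, key=lambda m: (bin(m).count("1"), self.genotype_string(m))):
            meas = self._data[mask]
            rows.append(
                {
                    "genotype": self.genotype_string(mask),
                    "mean_fold": meas.mean,
                    "sd": meas.sd,
                    "n": meas.n,
                }
            )
        return pd.DataFrame(rows, columns=["genotype", "mean_fold", "sd", "n"])


# -- I/O -------------------------------------------------------------------


def read_landscape(path: str | Path, name: str | None = None) -> FitnessLandscape:
    """Read a landscape CSV with header ``genotype,mean_fold,sd,n``.

    The substitution alphabet is inferred as the union of substitutions
    appearing across genotypes. Errors carry the 1-based file row number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"genotype": str}, keep_default_na=False)
    required = {"genotype", "mean_fold"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: landscape CSV needs columns {sorted(required)}")
    subs: set[Substitution] = set()
    parsed = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # header is row 1
        try:
            genotype = parse_genotype(str(row["genotype"]))
            mean = float(row["mean_fold"])
            sd = float(row.get("sd", 0.0) or 0.0)
            n = int(row.get("n", 1) or 1)
            meas = FitnessMeasurement(mean=mean, sd=sd, n=n)
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}, row {rowno}: {exc}") from exc
        subs.update(genotype)
        parsed.append((rowno, genotype, meas))
    by_pos: dict[int, Substitution] = {}
    for s in subs:
        if s.position in by_pos and by_pos[s.position] != s:
            raise ValueError(
                f"{path}: conflicting alleles {by_pos[s.position]} and {s} at position {s.position}"
            )
        by_pos[s.position] = s
    measurements: dict[str, FitnessMeasurement] = {}
    for rowno, genotype, meas in parsed:
        key = format_genotype(genotype)
        if key in measurements:
            raise ValueError(f"{path}, row {rowno}: duplicate genotype {key!r}")
        measurements[key] = meas
    return FitnessLandscape(sorted(by_pos.values()), measurements, name=name or path.stem)


def write_landscape(landscape: FitnessLandscape, path: str | Path) -> None:
    """Write the canonical landscape CSV (write . read is the identity)."""
    df = landscape.to_frame()
    df.to_csv(path, index=False, float_format="%.10g")


# -- fold improvement ------------------------------------------------------


def fold_improvement(variant_ec50: float, wt_ec50: float) -> float:
    """EC50 ratio variant/wild-type; >1 means improved detoxification."""
    if not (variant_ec50 > 0 and wt_ec50 > 0):
        raise ValueError("EC50 values must be positive")
    return variant_ec50 / wt_ec50


def fold_from_replicates(
    ec50s: pd.DataFrame,
    wt_genotype: str = WT_TOKEN,
) -> pd.DataFrame:
    """Collapse replicate EC50s to per-genotype fold-improvement summaries.

    Expects long format with columns ``genotype, replicate, batch, ec50_uM``.
    If batches are present and each batch contains a wild-type measurement,
    each variant replicate is divided by its own batch's wild-type EC50 and
    the per-batch ratios averaged — this mirrors assays where a wild-type
    control is run alongside every batch and cancels day effects. Without
    batch pairing, the ratio of grand means is used, with the SD from
    first-order error propagation of the two means.
    """
    required = {"genotype", "ec50_uM"}
    if not required.issubset(ec50s.columns):
        raise ValueError(f"replicate table needs columns {sorted(required)}")
    df = ec50s.copy()
    df["genotype"] = df["genotype"].astype(str).str.strip().replace({"": WT_TOKEN})
    if (df["ec50_uM"] <= 0).any():
        raise ValueError("EC50 values must be positive")
    has_batch = "batch" in df.columns and df["batch"].notna().all()
    wt = df[df["genotype"] == wt_genotype]
    if wt.empty:
        raise ValueError(f"no wild-type ({wt_genotype!r}) EC50s in replicate table")
    rows = []
    if has_batch and set(df["batch"]) == set(wt["batch"]):
        wt_by_batch = wt.groupby("batch")["ec50_uM"].mean()
        for genotype, grp in df.groupby("genotype", sort=True):
            ratios = grp["ec50_uM"] / grp["batch"].map(wt_by_batch)
            rows.append(
                {
                    "genotype": genotype,
                    "mean_fold": float(ratios.mean()),
                    "sd": float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0,
                    "n": int(len(ratios)),
                }
            )
    else:
        wt_mean = float(wt["ec50_uM"].mean())
        wt_sd = float(wt["ec50_uM"].std(ddof=1)) if len(wt) > 1 else 0.0
        for genotype, grp in df.groupby("genotype", sort=True):
            v_mean = float(grp["ec50_uM"].mean())
            v_sd = float(grp["ec50_uM"].std(ddof=1)) if len(grp) > 1 else 0.0
            ratio = v_mean / wt_mean
            sd = ratio * math.hypot(v_sd / v_mean, wt_sd / wt_mean)
            rows.append(
                {"genotype": genotype, "mean_fold": ratio, "sd": sd, "n": int(len(grp))}
            )
    return pd.DataFrame(rows, columns=["genotype", "mean_fold", "sd", "n"])


# -- summaries -------------------------------------------------------------


@dataclass(frozen=True)
class PartitionSummary:
    """Fitness summary of genotypes containing vs lacking one substitution."""

    substitution: Substitution
    with_mean: float
    with_sd: float
    with_n: int
    without_mean: float
    without_sd: float
    without_n: int


def partition_summary(
    landscape: FitnessLandscape, substitution: Substitution | str
) -> PartitionSummary:
    """Split all measured genotypes by presence of one substitution.

    The wild type counts in the "lacking" group; the two groups partition
    the measured genotypes. SDs are sample standard deviations across the
    per-genotype mean fitnesses (not replicate-level pooling): this asks how
    variable the genotype means themselves are within each group.
    """
    if isinstance(substitution, str):
        substitution = Substitution.parse(substitution)
    if substitution not in landscape._index:
        raise KeyError(f"substitution {substitution} is not part of landscape {landscape.name!r}")
    bit = 1 << landscape._index[substitution]
    with_vals, without_vals = [], []
    for mask in landscape.masks:
        (with_vals if mask & bit else without_vals).append(landscape.mean(mask))

    def _stats(vals: list[float]) -> tuple[float, float, int]:
        arr = np.asarray(vals, dtype=float)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        return float(arr.mean()), sd, len(arr)

    wm, ws, wn = _stats(with_vals)
    lm, ls, ln_ = _stats(without_vals)
    return PartitionSummary(substitution, wm, ws, wn, lm, ls, ln_)


def category_profile(
    variant_set: Sequence[Sequence[str]], design: LibraryDesign
) -> pd.DataFrame:
    """Side-chain-category percentages at each design position over a variant set.

    ``variant_set`` holds one residue per design position for each variant
    (a string like ``"YLCYVRVG"`` works). Returns a positions x categories
    DataFrame of percentages; each row sums to 100.
    """
    npos = len(design.sites)
    for v in variant_set:
        if len(v) != npos:
            raise ValueError(
                f"variant {''.join(v)!r} has {len(v)} residues but the design has {npos} positions"
            )
    categories = list(SIDE_CHAIN_CATEGORIES)
    counts = pd.DataFrame(
        0.0, index=[s.position for s in design.sites], columns=categories
    )
    for v in variant_set:
        for site, aa in zip(design.sites, v):
            counts.loc[site.position, side_chain_category(aa)] += 1
    profile = counts / len(variant_set) * 100.0
    profile.index.name = "position"
    return profile
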