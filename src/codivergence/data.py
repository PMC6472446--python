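"""Domain types and input handling for biallelic character data.

A "character" is one orthologous site with at most two states, called
red and green, including constant sites.  For a pair of populations the
data at one site are summarized by the allele counts
``(n1, r1), (n2, r2)``: the number of gene copies sampled from each
population and how many of those carry the red allele.  Because each
character is exchangeable under the coalescent, sites with identical
counts are interchangeable and are collapsed into weighted patterns.

Missing cells (gaps, ambiguity codes) simply reduce the number of
sampled copies at that site; a site missing entirely from one
population is retained with n = 0 for that population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import yaml

from .priors import BetaPrior, GammaPrior, PriorConfig

logger = logging.getLogger(__name__)

__all__ = [
    "AllelePattern",
    "ComparisonData",
    "ComparisonCollection",
    "RunConfig",
    "MCMCSettings",
    "DataSettings",
    "read_population_map",
    "read_alignment",
    "recode_to_binary",
    "aggregate_patterns",
    "comparison_from_alignment",
]

MISSING = -1
_NUCLEOTIDES = set("ACGT")
_IUPAC_AMBIGUOUS = set("RYSWKMBDHVN")
_MISSING_SYMBOLS = set("-?")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AllelePattern:
    """Allele counts at one site: (n1, r1), (n2, r2), with a multiplicity
    weight giving the number of sites sharing this pattern."""

    n1: int
    r1: int
    n2: int
    r2: int
    weight: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.r1 <= self.n1 and 0 <= self.r2 <= self.n2):
            raise ValueError(f"invalid allele counts {self}")
        if self.n1 + self.n2 < 1:
            raise ValueError("pattern must have at least one sampled copy")
        if self.weight < 1:
            raise ValueError("pattern weight must be >= 1")

    @property
    def is_constant(self) -> bool:
        r = self.r1 + self.r2
        return r == 0 or r == self.n1 + self.n2


@dataclass
class ComparisonData:
    """All retained character patterns for one pair of populations."""

    label: str
    patterns: list[AllelePattern]
    loci: Optional[list[tuple[str, int]]] = None
    constant_removed: bool = False
    polyallelic_policy_applied: str = "none"

    def __post_init__(self) -> None:
        if self.polyallelic_policy_applied not in ("recode", "remove", "none"):
            raise ValueError(
                f"unknown polyallelic policy {self.polyallelic_policy_applied!r}"
            )
        if self.constant_removed and any(p.is_constant for p in self.patterns):
            raise ValueError("constant pattern present but constant_removed is set")

    @property
    def max_copies(self) -> tuple[int, int]:
        if not self.patterns:
            return (0, 0)
        return (max(p.n1 for p in self.patterns), max(p.n2 for p in self.patterns))

    @property
    def total_weight(self) -> int:
        return sum(p.weight for p in self.patterns)

    @property
    def has_constant_patterns(self) -> bool:
        return any(p.is_constant for p in self.patterns)

    def drop_constant(self) -> "ComparisonData":
        """Return a copy with constant patterns excluded and the flag set."""
        kept = [p for p in self.patterns if not p.is_constant]
        return replace(self, patterns=kept, constant_removed=True)

    # -- plain-text round trip ---------------------------------------------

    def to_pattern_table(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("n1\tr1\tn2\tr2\tweight\n")
            for p in self.patterns:
                fh.write(f"{p.n1}\t{p.r1}\t{p.n2}\t{p.r2}\t{p.weight}\n")

    @classmethod
    def from_pattern_table(
        cls, path: Union[str, Path], label: str, **kwargs
    ) -> "ComparisonData":
        patterns = []
        with open(path) as fh:
            header = fh.readline().split()
            if header[:5] != ["n1", "r1", "n2", "r2", "weight"]:
                raise ValueError(f"unrecognized pattern table header in {path}")
            for line in fh:
                if not line.strip():
                    continue
                n1, r1, n2, r2, w = (int(x) for x in line.split())
                patterns.append(AllelePattern(n1, r1, n2, r2, w))
        return cls(label=label, patterns=patterns, **kwargs)


@dataclass
class ComparisonCollection:
    """Ordered collection of population pairs analyzed jointly."""

    comparisons: list[ComparisonData]

    def __post_init__(self) -> None:
        if len(self.comparisons) < 1:
            raise ValueError("need at least one comparison")
        labels = [c.label for c in self.comparisons]
        if len(set(labels)) != len(labels):
            raise ValueError("comparison labels must be unique")

    def __len__(self) -> int:
        return len(self.comparisons)

    def __iter__(self):
        return iter(self.comparisons)

    def __getitem__(self, i):
        return self.comparisons[i]

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.comparisons]


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MCMCSettings:
    generations: int = 75_000
    sample_interval: int = 50
    chains: int = 3
    seed: Optional[int] = None
    n_aux: int = 2
    size_window: float = 0.5
    time_window: float = 0.5
    mixer_window: float = 0.3
    pi_window: float = 0.1

    def __post_init__(self) -> None:
        if self.generations < 1 or self.sample_interval < 1 or self.chains < 1:
            raise ValueError("generations, sample_interval, chains must be >= 1")
        if self.generations % self.sample_interval != 0:
            raise ValueError("sample_interval must divide generations")
        if self.n_aux < 1:
            raise ValueError("n_aux must be >= 1")


@dataclass(frozen=True)
class DataSettings:
    use_constant_characters: bool = True
    polyallelic_policy: str = "recode"
    correction: str = "per_site"  # applied only when constants are excluded

    def __post_init__(self) -> None:
        if self.polyallelic_policy not in ("recode", "remove", "none"):
            raise ValueError(f"unknown polyallelic policy {self.polyallelic_policy!r}")
        if self.correction not in ("per_site", "max_copies", "none"):
            raise ValueError(f"unknown correction {self.correction!r}")


@dataclass(frozen=True)
class RunConfig:
    priors: PriorConfig = PriorConfig()
    mcmc: MCMCSettings = MCMCSettings()
    data: DataSettings = DataSettings()
    pairs: tuple = ()  # optional sequence of {label, alignment, popmap, format}

    @property
    def effective_correction(self) -> str:
        return "none" if self.data.use_constant_characters else self.data.correction

    # -- YAML schema --------------------------------------------------------

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def gamma_or_fixed(node, default):
            if node is None:
                return default
            if isinstance(node, (int, float)):
                return float(node)
            if "value" in node:
                return float(node["value"])
            dist = node.get("distribution", "gamma")
            shape = 1.0 if dist == "exponential" else float(node["shape"])
            return GammaPrior(shape, float(node["mean"]))

        p = PriorConfig()
        tau = gamma_or_fixed(raw.get("event_time_prior"), p.tau_prior)
        if not isinstance(tau, GammaPrior):
            raise ValueError("event_time_prior must be a distribution, not a value")
        leaf = gamma_or_fixed(raw.get("leaf_population_size_prior"), p.descendant_size_prior)
        root = gamma_or_fixed(
            raw.get("root_relative_population_size_prior"), p.relative_root_size_prior
        )
        freq = raw.get("freq_1", 0.5)
        if isinstance(freq, dict) and "value" in freq:
            freq = float(freq["value"])
        elif isinstance(freq, dict):
            freq = BetaPrior(float(freq["alpha"]), float(freq["beta"]))
        else:
            freq = float(freq)
        conc = raw.get("concentration", p.alpha)
        if isinstance(conc, dict) and "value" not in conc:
            conc = GammaPrior(float(conc["shape"]), float(conc["mean"]))
        elif isinstance(conc, dict):
            conc = float(conc["value"])
        else:
            conc = float(conc)
        priors = PriorConfig(
            tau_prior=tau,
            descendant_size_prior=leaf,
            relative_root_size_prior=root,
            pi_prior=freq,
            alpha=conc,
        )
        mcmc = MCMCSettings(**raw.get("mcmc", {}))
        data = DataSettings(**raw.get("data", {}))
        pairs = tuple(raw.get("pairs", ()))
        return cls(priors=priors, mcmc=mcmc, data=data, pairs=pairs)

    def to_dict(self) -> dict:
        def prior_node(pr):
            if isinstance(pr, GammaPrior):
                return {"distribution": "gamma", "shape": pr.shape, "mean": pr.mean}
            return {"value": pr}

        pc = self.priors
        out = {
            "event_time_prior": prior_node(pc.tau_prior),
            "leaf_population_size_prior": prior_node(pc.descendant_size_prior),
            "root_relative_population_size_prior": prior_node(pc.relative_root_size_prior),
            "freq_1": (
                {"alpha": pc.pi_prior.alpha, "beta": pc.pi_prior.beta}
                if isinstance(pc.pi_prior, BetaPrior)
                else pc.pi_prior
            ),
            "concentration": (
                {"shape": pc.alpha.shape, "mean": pc.alpha.mean}
                if isinstance(pc.alpha, GammaPrior)
                else {"value": pc.alpha}
            ),
            "mcmc": {
                "generations": self.mcmc.generations,
                "sample_interval": self.mcmc.sample_interval,
                "chains": self.mcmc.chains,
                "seed": self.mcmc.seed,
                "n_aux": self.mcmc.n_aux,
            },
            "data": {
                "use_constant_characters": self.data.use_constant_characters,
                "polyallelic_policy": self.data.polyallelic_policy,
                "correction": self.data.correction,
            },
        }
        if self.pairs:
            out["pairs"] = list(self.pairs)
        return out

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Alignment reading
# ---------------------------------------------------------------------------

def read_population_map(path: Union[str, Path]) -> dict[str, str]:
    """Two-column tab-separated file mapping sequence id -> population."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"malformed population map line: {line!r}")
            mapping[fields[0]] = fields[1]
    return mapping


def read_alignment(
    path: Union[str, Path],
    population_map: dict[str, str],
    format: str = "nexus",
) -> tuple[list[str], list[str], np.ndarray]:
    """Read an alignment and tag each sequence with its population.

    Returns ``(sequence_ids, population_labels, matrix)`` where matrix is
    a 2-D array of single-character state symbols (upper-case), one row
    per sequence.  Gaps and ambiguity codes are left in place; they are
    interpreted as missing cells downstream.
    """
    import dendropy

    path = str(path)
    if format not in ("nexus", "fasta"):
        raise ValueError(f"unsupported alignment format {format!r}")
    if format == "nexus":
        ds = dendropy.DataSet.get(path=path, schema="nexus")
        if not ds.char_matrices:
            raise ValueError(f"no character matrix found in {path}")
        cm = ds.char_matrices[0]
    else:
        cm = dendropy.DnaCharacterMatrix.get(path=path, schema="fasta")

    ids: list[str] = []
    rows: list[list[str]] = []
    for taxon in cm:
        ids.append(taxon.label)
        rows.append([str(c) .upper() for c in cm[taxon].symbols_as_list()])
    if not ids or not rows or not rows[0]:
        raise ValueError(f"empty alignment in {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment in {path}")

    pops = []
    for sid in ids:
        if sid not in population_map:
            raise KeyError(f"sequence id {sid!r} missing from population map")
        pops.append(population_map[sid])
    pop_labels = sorted(set(pops))
    if len(pop_labels) != 2:
        raise ValueError(
            f"expected exactly two population labels, got {pop_labels}"
        )
    return ids, pops, np.array(rows, dtype="U1")


# ---------------------------------------------------------------------------
# Recoding and aggregation
# ---------------------------------------------------------------------------

def _is_missing(sym: str) -> bool:
    return sym in _MISSING_SYMBOLS or sym in _IUPAC_AMBIGUOUS


def recode_to_binary(
    column: Sequence[str], policy: str = "recode_first_as_green"
) -> Optional[np.ndarray]:
    """Recode one site column to 0 (green) / 1 (red) / -1 (missing).

    Nucleotide columns are recoded by treating the first non-missing
    nucleotide, scanning sequences in file order, as green and every
    other nucleotide as red.  Under ``remove_polyallelic`` a column with
    more than two distinct nucleotides returns None instead.  Binary
    input passes through unchanged.
    """
    if policy not in ("recode_first_as_green", "remove_polyallelic"):
        raise ValueError(f"unknown recoding policy {policy!r}")
    syms = [str(c).upper() for c in column]
    out = np.empty(len(syms), dtype=np.int8)
    observed: list[str] = []
    binary = True
    for i, s in enumerate(syms):
        if s in ("0", "1"):
            out[i] = int(s)
            continue
        binary = False
        if _is_missing(s):
            out[i] = MISSING
            continue
        if s not in _NUCLEOTIDES:
            raise ValueError(f"unrecognized state symbol {s!r}")
        if s not in observed:
            observed.append(s)
        out[i] = 0 if s == observed[0] else 1
    if binary:
        for i, s in enumerate(syms):
            if s not in ("0", "1"):
                out[i] = MISSING
        return out
    if len(observed) > 2 and policy == "remove_polyallelic":
        return None
    return out


def aggregate_patterns(
    columns: Iterable[np.ndarray],
    populations: Sequence[str],
    drop_constant: bool = False,
    label: str = "pair",
    loci: Optional[list[tuple[str, int]]] = None,
    polyallelic_policy_applied: str = "none",
) -> ComparisonData:
    """Collapse binary site columns into weighted allele-count patterns.

    ``populations`` assigns each row to one of two labels (sorted order
    decides which is population 1).  Sites with zero sampled copies in
    both populations cannot contribute and are dropped with a warning.
    """
    pops = np.asarray(populations)
    pop_labels = sorted(set(pops.tolist()))
    if len(pop_labels) != 2:
        raise ValueError("exactly two populations required")
    mask1 = pops == pop_labels[0]
    mask2 = pops == pop_labels[1]

    keys: dict[tuple[int, int, int, int], int] = {}
    n_dropped = 0
    for col in columns:
        col = np.asarray(col)
        ok = col != MISSING
        n1 = int(np.count_nonzero(ok & mask1))
        n2 = int(np.count_nonzero(ok & mask2))
        if n1 + n2 == 0:
            n_dropped += 1
            continue
        r1 = int(col[ok & mask1].sum())
        r2 = int(col[ok & mask2].sum())
        key = (n1, r1, n2, r2)
        keys[key] = keys.get(key, 0) + 1
    if n_dropped:
        logger.warning(
            "%s: dropped %d sites with zero sampled copies in both populations",
            label,
            n_dropped,
        )

    patterns = [
        AllelePattern(n1, r1, n2, r2, w) for (n1, r1, n2, r2), w in sorted(keys.items())
    ]
    data = ComparisonData(
        label=label,
        patterns=patterns,
        loci=loci,
        constant_removed=False,
        polyallelic_policy_applied=polyallelic_policy_applied,
    )
    if drop_constant:
        data = data.drop_constant()
    return data


def comparison_from_alignment(
    path: Union[str, Path],
    population_map: Union[str, Path, dict[str, str]],
    format: str = "nexus",
    polyallelic_policy: str = "recode",
    drop_constant: bool = False,
    label: Optional[str] = None,
) -> ComparisonData:
    """Read, recode and aggregate one pair's alignment in a single step."""
    if not isinstance(population_map, dict):
        population_map = read_population_map(population_map)
    ids, pops, matrix = read_alignment(path, population_map, format=format)
    policy = {
        "recode": "recode_first_as_green",
        "remove": "remove_polyallelic",
        "none": "recode_first_as_green",
    }[polyallelic_policy]
    cols = []
    for j in range(matrix.shape[1]):
        col = recode_to_binary(matrix[:, j], policy=policy)
        if col is not None:
            cols.append(col)
    return aggregate_patterns(
        cols,
        pops,
        drop_constant=drop_constant,
        label=label or Path(path).stem,
        polyallelic_policy_applied=polyallelic_policy,
    )
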