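import numpy as np
import pytest

from codivergence.data import (
    MISSING,
    AllelePattern,
    ComparisonCollection,
    ComparisonData,
    DataSettings,
    MCMCSettings,
    RunConfig,
    aggregate_patterns,
    comparison_from_alignment,
    read_alignment,
    read_population_map,
    recode_to_binary,
)
from codivergence.priors import GammaPrior


class TestAllelePattern:
    def test_valid(self):
        p = AllelePattern(4, 2, 3, 0, 5)
        assert not p.is_constant
        assert AllelePattern(4, 0, 3, 0).is_constant
        assert AllelePattern(4, 4, 3, 3).is_constant
        # one population entirely unsampled is allowed
        assert AllelePattern(0, 0, 3, 1).weight == 1

    def test_invalid(self):
        with pytest.raises(ValueError):
            AllelePattern(4, 5, 3, 0)  # more red copies than samples
        with pytest.raises(ValueError):
            AllelePattern(-1, 0, 3, 0)
        with pytest.raises(ValueError):
            AllelePattern(0, 0, 0, 0)  # no samples at all
        with pytest.raises(ValueError):
            AllelePattern(4, 2, 3, 1, 0)  # zero weight


class TestComparisonData:
    def test_properties(self, small_data):
        assert small_data.max_copies == (4, 4)
        assert small_data.total_weight == 24
        assert small_data.has_constant_patterns

    def test_drop_constant(self, small_data):
        reduced = small_data.drop_constant()
        assert reduced.constant_removed
        assert not reduced.has_constant_patterns
        assert reduced.total_weight == 6

    def test_pattern_table_round_trip(self, small_data, tmp_path):
        path = tmp_path / "patterns.tsv"
        small_data.to_pattern_table(path)
        back = ComparisonData.from_pattern_table(path, label="toy")
        assert back.label == "toy"
        assert sorted(
            (p.n1, p.r1, p.n2, p.r2, p.weight) for p in back.patterns
        ) == sorted((p.n1, p.r1, p.n2, p.r2, p.weight) for p in small_data.patterns)

    def test_collection_requires_unique_labels(self, small_data):
        with pytest.raises(ValueError):
            ComparisonCollection([small_data, small_data])
        coll = ComparisonCollection([small_data])
        assert coll.labels == ["toy"]
        assert len(coll) == 1


class TestRecodeToBinary:
    def test_binary_passthrough(self):
        out = recode_to_binary(list("0110?-"))
        assert out.tolist() == [0, 1, 1, 0, MISSING, MISSING]

    def test_nucleotide_first_is_green(self):
        out = recode_to_binary(list("AAGGA"))
        assert out.tolist() == [0, 0, 1, 1, 0]
        # leading missing cells do not set the green state
        out = recode_to_binary(list("?GAAG"))
        assert out.tolist() == [MISSING, 0, 1, 1, 0]

    def test_ambiguity_codes_are_missing(self):
        out = recode_to_binary(list("ARAN-T"))
        assert out.tolist() == [0, MISSING, 0, MISSING, MISSING, 1]

    def test_polyallelic_policies(self):
        col = list("ACGT")
        recoded = recode_to_binary(col, policy="recode_first_as_green")
        assert recoded.tolist() == [0, 1, 1, 1]
        assert recode_to_binary(col, policy="remove_polyallelic") is None
        # two alleles survive the remove policy
        assert recode_to_binary(list("ACCA"), policy="remove_polyallelic") is not None

    def test_errors(self):
        with pytest.raises(ValueError):
            recode_to_binary(list("AX"))
        with pytest.raises(ValueError):
            recode_to_binary(list("AC"), policy="bogus")


class TestAggregatePatterns:
    def test_hand_case(self):
        pops = ["a", "a", "b", "b", "b"]
        cols = [
            np.array([0, 1, 0, 0, 1], dtype=np.int8),
            np.array([0, 1, 0, 0, 1], dtype=np.int8),  # same pattern
            np.array([MISSING, 1, 0, MISSING, 1], dtype=np.int8),
        ]
        data = aggregate_patterns(cols, pops, label="x")
        got = {(p.n1, p.r1, p.n2, p.r2): p.weight for p in data.patterns}
        assert got == {(2, 1, 3, 1): 2, (1, 1, 2, 1): 1}

    def test_population_order_is_sorted(self):
        pops = ["zebra", "ant", "ant"]
        cols = [np.array([1, 0, 0], dtype=np.int8)]
        data = aggregate_patterns(cols, pops, label="x")
        p = data.patterns[0]
        # "ant" sorts first so it is population 1 (two copies, zero red)
        assert (p.n1, p.r1, p.n2, p.r2) == (2, 0, 1, 1)

    def test_all_missing_sites_dropped(self, caplog):
        pops = ["a", "b"]
        cols = [
            np.array([MISSING, MISSING], dtype=np.int8),
            np.array([0, 1], dtype=np.int8),
        ]
        data = aggregate_patterns(cols, pops, label="x")
        assert data.total_weight == 1

    def test_drop_constant_flag(self):
        pops = ["a", "b"]
        cols = [np.array([0, 0], dtype=np.int8), np.array([0, 1], dtype=np.int8)]
        data = aggregate_patterns(cols, pops, drop_constant=True)
        assert data.constant_removed
        assert data.total_weight == 1


NEXUS = """#NEXUS
BEGIN DATA;
    DIMENSIONS NTAX=4 NCHAR=5;
    FORMAT DATATYPE=DNA MISSING=? GAP=-;
    MATRIX
        s1  ACGTA
        s2  ACGTC
        s3  ATG?T
        s4  ATGTA
    ;
END;
"""

FASTA = """>s1
ACGTA
>s2
ACGTC
>s3
ATG?T
>s4
ATGTA
"""


class TestAlignments:
    @pytest.fixture
    def popmap_file(self, tmp_path):
        path = tmp_path / "popmap.tsv"
        path.write_text("s1\tnorth\ns2\tnorth\ns3\tsouth\ns4\tsouth\n")
        return path

    def test_read_population_map(self, popmap_file):
        mapping = read_population_map(popmap_file)
        assert mapping == {
            "s1": "north", "s2": "north", "s3": "south", "s4": "south"
        }

    def test_read_alignment_nexus(self, tmp_path, popmap_file):
        path = tmp_path / "a.nex"
        path.write_text(NEXUS)
        ids, pops, matrix = read_alignment(
            path, read_population_map(popmap_file)
        )
        assert matrix.shape == (4, 5)
        assert sorted(set(pops)) == ["north", "south"]

    def test_read_alignment_fasta_matches_nexus(self, tmp_path, popmap_file):
        nex = tmp_path / "a.nex"
        nex.write_text(NEXUS)
        fas = tmp_path / "a.fasta"
        fas.write_text(FASTA)
        popmap = read_population_map(popmap_file)
        d1 = comparison_from_alignment(nex, popmap, format="nexus", label="x")
        d2 = comparison_from_alignment(fas, popmap, format="fasta", label="x")
        key = lambda d: sorted(
            (p.n1, p.r1, p.n2, p.r2, p.weight) for p in d.patterns
        )
        assert key(d1) == key(d2)

    def test_missing_popmap_entry_raises(self, tmp_path):
        path = tmp_path / "a.nex"
        path.write_text(NEXUS)
        with pytest.raises(KeyError):
            read_alignment(path, {"s1": "north"})

    def test_comparison_from_alignment_counts(self, tmp_path, popmap_file):
        path = tmp_path / "a.nex"
        path.write_text(NEXUS)
        data = comparison_from_alignment(path, popmap_file, label="pairA")
        assert data.label == "pairA"
        # the last column (A/C/T) is polyallelic; recode keeps it
        assert data.total_weight == 5
        removed = comparison_from_alignment(
            path, popmap_file, polyallelic_policy="remove", label="pairA"
        )
        assert removed.total_weight == 4


class TestRunConfig:
    def test_defaults(self):
        cfg = RunConfig.from_dict({"pairs": []})
        assert cfg.priors.tau_prior.shape == 1.0
        assert cfg.priors.alpha == pytest.approx(1.414216)
        assert cfg.mcmc.generations == 75000
        assert cfg.data.use_constant_characters

    def test_effective_correction(self):
        cfg = RunConfig.from_dict(
            {"pairs": [], "data": {"use_constant_characters": True}}
        )
        assert cfg.effective_correction == "none"
        cfg2 = RunConfig.from_dict(
            {"pairs": [], "data": {"use_constant_characters": False,
                                   "correction": "per_site"}}
        )
        assert cfg2.effective_correction == "per_site"

    def test_exponential_is_gamma_shape_one(self):
        cfg = RunConfig.from_dict(
            {
                "pairs": [],
                "event_time_prior": {"distribution": "exponential", "mean": 0.05},
            }
        )
        assert cfg.priors.tau_prior.shape == 1.0
        assert cfg.priors.tau_prior.mean == pytest.approx(0.05)

    def test_fixed_values(self):
        cfg = RunConfig.from_dict(
            {
                "pairs": [],
                "freq_1": {"value": 0.5},
                "concentration": {"distribution": "gamma", "shape": 2.0,
                                  "mean": 1.5},
            }
        )
        assert cfg.priors.pi_prior == 0.5
        assert isinstance(cfg.priors.alpha, GammaPrior)
        assert cfg.priors.alpha.mean == pytest.approx(1.5)

    def test_yaml_round_trip(self, tmp_path):
        cfg = RunConfig.from_dict(
            {
                "pairs": [{"label": "p0", "patterns": "p0.tsv"}],
                "event_time_prior": {"distribution": "gamma", "shape": 2.0,
                                     "mean": 0.05},
                "mcmc": {"generations": 500, "sample_interval": 10,
                         "chains": 2, "seed": 42},
            }
        )
        path = tmp_path / "cfg.yml"
        cfg.to_yaml(path)
        back = RunConfig.from_yaml(path)
        assert back.to_dict() == cfg.to_dict()

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            MCMCSettings(generations=0)
        with pytest.raises(ValueError):
            DataSettings(correction="bogus")
        with pytest.raises(ValueError):
            DataSettings(polyallelic_policy="bogus")
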