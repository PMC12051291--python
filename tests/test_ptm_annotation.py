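import numpy as np
import pytest

from ptmbind import FixtureSpec, make_toy_complex
from ptmbind.ptm_annotation import (
    DomainRange,
    PTMSite,
    find_proximal_ptms,
    map_sites_to_domains,
    parse_range_string,
    read_ptm_table,
    validate_sites,
)
from ptmbind.seq_align import map_chain_to_reference
from ptmbind.structures_io import chain_sequence

from .oracles import all_pairs_min_distances


def _write_tsv(tmp_path, rows, header="accession\tposition\tresidue\tptm_type"):
    p = tmp_path / "ptms.tsv"
    p.write_text(header + "\n" + "\n".join("\t".join(r) for r in rows) + "\n")
    return p


class TestReadPTMTable:
    def test_duplicates_collapse(self, tmp_path):
        rows = [
            ("P1", "3", "S", "Phosphorylation"),
            ("P1", "3", "S", "Phosphorylation"),
            ("P1", "7", "K", "Acetylation"),
        ]
        sites = read_ptm_table(_write_tsv(tmp_path, rows))
        assert len(sites) == 2

    def test_non_integer_position_rejected(self, tmp_path, caplog):
        rows = [("P1", "abc", "S", "Phosphorylation")]
        with caplog.at_level("WARNING"):
            sites = read_ptm_table(_write_tsv(tmp_path, rows))
        assert sites == []
        assert any("rejected" in r.message for r in caplog.records)

    def test_two_accessions_two_sites_each(self, tmp_path):
        rows = [
            ("P1", "3", "S", "Phosphorylation"),
            ("P1", "7", "K", "Acetylation"),
            ("P2", "3", "S", "Phosphorylation"),
            ("P2", "9", "Y", "Phosphorylation"),
        ]
        sites = read_ptm_table(_write_tsv(tmp_path, rows))
        assert len(sites) == 4
        assert {s.accession for s in sites} == {"P1", "P2"}

    def test_positional_columns(self, tmp_path):
        p = tmp_path / "pos.tsv"
        p.write_text("GENE1\tP1\t3\tS\tPhosphorylation\n")
        sites = read_ptm_table(
            p, columns={"accession": 1, "position": 2, "residue": 3,
                        "ptm_type": 4},
        )
        assert len(sites) == 1 and sites[0].position == 3


class TestValidateSites:
    def test_status_assignment(self):
        sites = [
            PTMSite("P1", 3, "S", "Phosphorylation"),
            PTMSite("P1", 3, "T", "Phosphorylation"),
            PTMSite("P1", 9, "S", "Phosphorylation"),
        ]
        validate_sites(sites, "AGS")
        assert [s.status for s in sites] == \
            ["valid", "residue_mismatch", "unmapped"]

    def test_mismatches_logged(self, caplog):
        with caplog.at_level("WARNING"):
            validate_sites([PTMSite("P1", 3, "T", "Ph")], "AGS")
        assert any("excluded" in r.message for r in caplog.records)

    def test_count_never_changes(self):
        sites = [PTMSite("P1", i, "A", "x") for i in range(1, 6)]
        assert len(validate_sites(sites, "AAA")) == 5


class TestFindProximalPTMs:
    @staticmethod
    def _annotate(toy, cutoff):
        ref = toy.reference
        cs = chain_sequence(ref, "A")
        rmap = map_chain_to_reference(cs, toy.ref_seq)
        sites = [
            PTMSite(toy.spec.accession, pos, res, ptm, status="valid")
            for pos, res, ptm, _d in toy.spec.planted_sites
        ]
        return find_proximal_ptms(ref, ref.ligands[0], sites, rmap,
                                  cutoff=cutoff)

    def test_planted_distances_recovered(self, toy):
        hits = self._annotate(toy, cutoff=10.0)
        got = {h.site.position: h.min_distance for h in hits}
        want = {
            pos: d for pos, _r, _p, d in toy.spec.planted_sites if d <= 10.0
        }
        assert got.keys() == want.keys()
        for pos in want:
            assert got[pos] == pytest.approx(want[pos], abs=1e-6)

    def test_distal_site_excluded(self, toy):
        positions = {h.site.position for h in self._annotate(toy, 10.0)}
        assert 18 not in positions  # planted at 12 Å

    def test_boundary_inclusive(self):
        toy = make_toy_complex(FixtureSpec(
            seed=4, planted_sites=[(10, "S", "Phosphorylation", 10.0)],
        ))
        hits = self._annotate(toy, cutoff=10.0)
        assert len(hits) == 1
        assert hits[0].min_distance == pytest.approx(10.0, abs=1e-6)

    def test_monotone_in_cutoff(self, toy):
        sets = [
            {h.site.position for h in self._annotate(toy, c)}
            for c in (8.0, 10.0, 12.0)
        ]
        assert sets[0] <= sets[1] <= sets[2]

    def test_invalid_sites_never_searched(self, toy):
        ref = toy.reference
        rmap = map_chain_to_reference(chain_sequence(ref, "A"), toy.ref_seq)
        site = PTMSite(toy.spec.accession, 10, "S", "Ph",
                       status="residue_mismatch")
        assert find_proximal_ptms(ref, ref.ligands[0], [site], rmap) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_all_pairs_scan(self, seed):
        """Tree-backed search equals the dense O(N*M) distance scan."""
        rng = np.random.default_rng(seed)
        d1, d2 = sorted(rng.uniform(2.0, 13.0, 2))
        toy = make_toy_complex(FixtureSpec(
            seed=seed,
            planted_sites=[(10, "S", "Phosphorylation", float(d1)),
                           (18, "T", "Phosphorylation", float(d2))],
        ))
        ref = toy.reference
        cutoff = float(rng.uniform(3.0, 14.0))
        hits = self._annotate(toy, cutoff)
        got = {h.site.position: h.min_distance for h in hits}

        chain = ref.chains[0]
        res_coords = {
            r.key: [a.coord for a in r.atoms] for r in chain.residues
        }
        oracle = all_pairs_min_distances(res_coords, ref.ligands[0].coords())
        rmap = map_chain_to_reference(chain_sequence(ref, "A"), toy.ref_seq)
        pos2key = rmap.position_to_key()
        want = {
            pos: oracle[pos2key[pos]]
            for pos, _r, _p, _d in toy.spec.planted_sites
            if oracle[pos2key[pos]] <= cutoff
        }
        assert got.keys() == want.keys()
        for pos in got:
            assert got[pos] == pytest.approx(want[pos], abs=1e-9)


class TestDomains:
    def test_range_string_parsing(self):
        d = parse_range_string("D1", "P1", "A:12-150,A:200-240")
        assert d.segments == [(12, 150), (200, 240)]
        assert parse_range_string("D2", "P1", "A:57").segments == [(57, 57)]

    def test_single_domain_assignment(self):
        d1 = DomainRange("D1", "P1", [(12, 150)])
        s_in = PTMSite("P1", 50, "S", "Ph")
        s_out = PTMSite("P1", 5, "S", "Ph")
        out = map_sites_to_domains([s_in, s_out], [d1])
        assert out[id(s_in)] == ["D1"]
        assert out[id(s_out)] == []

    def test_overlapping_domains_assign_all(self, caplog):
        doms = [DomainRange("D1", "P1", [(1, 30)]),
                DomainRange("D2", "P1", [(15, 40)])]
        s = PTMSite("P1", 20, "S", "Ph")
        with caplog.at_level("WARNING"):
            out = map_sites_to_domains([s], doms)
        assert out[id(s)] == ["D1", "D2"]
        assert any("overlapping" in r.message for r in caplog.records)

    def test_inverted_segment_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            DomainRange("D1", "P1", [(10, 5)])
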