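import json

import numpy as np
import pytest

import pepgrasp as pg
from pepgrasp.index import (
    SENTINEL,
    EmptyDatabaseError,
    IndexFormatError,
    Provenance,
    _link_eligible_ids,
)
from oracles import brute_lcp, brute_suffix_array, mes_overlaps, random_protein, sampled_read_db


class TestPeptideDatabase:
    def test_offsets_and_text(self):
        db = pg.PeptideDatabase(["ACD", "EF"])
        assert db.offsets == [0, 4]
        assert db.text == "ACD" + SENTINEL + "EF" + SENTINEL
        assert len(db.text) == sum(len(r) + 1 for r in db.reads)

    def test_rejects_empty_read(self):
        with pytest.raises(ValueError):
            pg.PeptideDatabase([""])

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError):
            pg.PeptideDatabase(["AA", "CC"], ["r", "r"])

    def test_read_at_text_pos(self):
        db = pg.PeptideDatabase(["ACD", "EF"], ["a", "b"])
        assert db.read_at_text_pos(0) == ("a", 0)
        assert db.read_at_text_pos(5) == ("b", 1)
        with pytest.raises(ValueError):
            db.read_at_text_pos(3)  # sentinel


class TestSuffixIndex:
    def test_empty_database_rejected(self):
        with pytest.raises(EmptyDatabaseError):
            pg.build_suffix_index(pg.PeptideDatabase([]))

    def test_single_read(self):
        db = pg.PeptideDatabase(["AC"])
        idx = pg.build_suffix_index(db)
        text = db.text
        suffixes = [text[i:] for i in idx.suffix_array]
        assert suffixes == sorted(text[i:] for i in range(len(text)))

    @pytest.mark.parametrize("trial", range(10))
    def test_sortedness_and_lcp_vs_brute_force(self, trial):
        rng = np.random.default_rng(100 + trial)
        db = sampled_read_db(rng, 5, source_len=40, min_len=5, max_len=12)
        idx = pg.build_suffix_index(db)
        text = db.text
        assert idx.suffix_array.tolist() == brute_suffix_array(text)
        assert idx.lcp_array.tolist() == brute_lcp(text, idx.suffix_array.tolist())


class TestExtensionLinks:
    def test_single_read_no_links(self):
        db = pg.PeptideDatabase(["ACDEFGHIKLMNP"])
        table = pg.build_extension_links(db, min_overlap=10)
        assert table.links == {}

    def test_unique_right_mes(self, rng):
        protein = random_protein(rng, 20)
        db = pg.PeptideDatabase([protein[0:15], protein[5:20]], ["r1", "r2"])
        table = pg.build_extension_links(db, min_overlap=10, direction="right")
        assert table.links == {"r1": [("r2", 10)]}
        # brute-force MES enumeration agrees
        assert pg.brute_force_mes("r1", db, 10, "right") == {("r2", 10)}

    def test_left_direction_mirrors(self, rng):
        protein = random_protein(rng, 20)
        db = pg.PeptideDatabase([protein[0:15], protein[5:20]], ["r1", "r2"])
        table = pg.build_extension_links(db, min_overlap=10, direction="left")
        assert table.links == {"r2": [("r1", 10)]}

    def test_link_overlaps_are_exact(self, rng):
        db = sampled_read_db(rng, 30)
        table = pg.build_extension_links(db, min_overlap=10, direction="right")
        for src, sinks in table.links.items():
            s = db.sequence(src)
            for sid, ov in sinks:
                assert s[-ov:] == db.sequence(sid)[:ov]
                assert ov >= 10

    def test_fanout_truncated_to_max_links(self):
        # 25 sinks sharing the same 10-aa prefix, each with a distinct extension
        prefix = "ACDEFGHIKL"
        tails = ["MNPQRSTVWY", "MNPQRSTVWA", "MNPQRSTVWC", "MNPQRSTVWD", "MNPQRSTVWE",
                 "MNPQRSTVWF", "MNPQRSTVWG", "MNPQRSTVWH", "MNPQRSTVWI", "MNPQRSTVWK",
                 "MNPQRSTVWL", "MNPQRSTVWM", "MNPQRSTVWN", "MNPQRSTVWP", "MNPQRSTVWQ",
                 "MNPQRSTVWR", "MNPQRSTVWS", "MNPQRSTVWT", "MNPQRSTVWV", "MNPQRSTVWW",
                 "MNPQRSTAWY", "MNPQRSTCWY", "MNPQRSTDWY", "MNPQRSTEWY", "MNPQRSTFWY"]
        assert len(tails) == len(set(tails)) == 25
        reads = ["WYVTSRQPNM" + prefix] + [prefix + t for t in tails]
        ids = ["src"] + [f"sink_{i}" for i in range(25)]
        db = pg.PeptideDatabase(reads, ids)
        unlimited = pg.build_extension_links(db, min_overlap=10, max_links=None)
        assert len(unlimited.links["src"]) == 25
        capped = pg.build_extension_links(db, min_overlap=10, max_links=20)
        assert len(capped.links["src"]) == 20
        # deterministic: longest overlaps first, ties by ascending id
        kept = capped.links["src"]
        assert kept == sorted(kept, key=lambda p: (-p[1], p[0]))[:20]

    def test_identical_reads_emit_no_mutual_links(self):
        db = pg.PeptideDatabase(["ACDEFGHIKLMN", "ACDEFGHIKLMN"], ["a", "b"])
        table = pg.build_extension_links(db, min_overlap=10)
        assert table.links == {}
        assert pg.brute_force_mes("a", db, 10) == set()
        assert pg.brute_force_mes("b", db, 10) == set()

    def test_contained_reads_excluded(self):
        db = pg.PeptideDatabase(["ACDEFGHIKLMNPQRS", "CDEFGHIKLM"], ["big", "small"])
        assert _link_eligible_ids(db, 10) == ["big"]

    def test_no_overlap_empty_oracle(self, rng):
        db = pg.PeptideDatabase([random_protein(rng, 15), random_protein(rng, 15)], ["a", "b"])
        # random 15-mers essentially never share a 10-aa overlap
        assert pg.brute_force_mes("a", db, 14) == set()

    @pytest.mark.parametrize("direction", ["right", "left"])
    @pytest.mark.parametrize("trial", range(20))
    def test_oracle_equivalence_random_dbs(self, trial, direction):
        rng = np.random.default_rng(1000 + trial)
        db = sampled_read_db(rng, 10)
        table = pg.build_extension_links(db, min_overlap=10, max_links=None, direction=direction)
        for rid in db.read_ids:
            got = set(table.links.get(rid, []))
            assert got == pg.brute_force_mes(rid, db, 10, direction)

    @pytest.mark.parametrize("direction", ["right", "left"])
    def test_brute_force_mes_cross_checked_by_test_oracle(self, direction):
        # brute_force_mes is itself the package-level oracle; validate it
        # once more against a fully test-side enumeration
        rng = np.random.default_rng(321)
        db = sampled_read_db(rng, 15)
        eligible = _link_eligible_ids(db, 10)
        for rid in eligible:
            others = {oid: db.sequence(oid) for oid in eligible if oid != rid}
            want = mes_overlaps(db.sequence(rid), others, 10, direction)
            assert pg.brute_force_mes(rid, db, 10, direction) == want

    def test_construction_ops_scale_linearly(self):
        rng = np.random.default_rng(7)
        ratios = []
        for n_reads in (50, 100, 200, 400):
            db = sampled_read_db(rng, n_reads, source_len=30 * n_reads)
            table = pg.build_extension_links(db, min_overlap=10)
            ratios.append(table.ops / db.total_residues)
        # operation count per residue stays bounded as the database doubles
        assert max(ratios) <= 3 * min(ratios)
        assert max(ratios) < 50


class TestSeedIndex:
    def test_short_read_contributes_nothing(self, alphabet):
        db = pg.PeptideDatabase(["ACDEF"])
        idx = pg.build_seed_index(db, alphabet, k=6)
        assert idx.n_occurrences == 0

    def test_read_of_length_k(self, alphabet):
        db = pg.PeptideDatabase(["ACDEFG"])
        idx = pg.build_seed_index(db, alphabet, k=6)
        assert idx.n_occurrences == 1
        assert idx.lookup(pg.reduce_sequence("ACDEFG", alphabet)) == [("read_0", 0)]

    def test_total_occurrence_count(self, rng, alphabet):
        db = sampled_read_db(rng, 20)
        idx = pg.build_seed_index(db, alphabet, k=6)
        expected = sum(max(0, len(r) - 5) for r in db.reads)
        assert idx.n_occurrences == expected

    def test_occurrences_match_keys(self, rng, alphabet):
        db = sampled_read_db(rng, 10)
        idx = pg.build_seed_index(db, alphabet, k=6)
        for key, occs in idx.table.items():
            for rid, off in occs:
                assert pg.reduce_sequence(db.sequence(rid)[off:off + 6], alphabet) == key

    def test_wildcard_kmers_skipped(self, alphabet):
        db = pg.PeptideDatabase(["ACDXEFGHIK"])
        idx = pg.build_seed_index(db, alphabet, k=6)
        for key in idx.table:
            assert alphabet.wildcard_letter not in key


class TestSaveLoad:
    def _bundle(self, rng, n=20):
        db = sampled_read_db(rng, n)
        db.provenance["read_0"] = Provenance("src", 0, len(db.reads[0]))
        return pg.build_index(db)

    def test_round_trip(self, rng, tmp_path):
        bundle = self._bundle(rng)
        path = pg.save_index(bundle, tmp_path / "idx")
        loaded = pg.load_index(tmp_path / "idx")
        assert loaded.db.reads == bundle.db.reads
        assert loaded.db.provenance == bundle.db.provenance
        assert loaded.suffix.suffix_array.tolist() == bundle.suffix.suffix_array.tolist()
        assert loaded.links_right.to_dict() == bundle.links_right.to_dict()
        assert loaded.links_left.to_dict() == bundle.links_left.to_dict()
        assert loaded.seeds.to_dict() == bundle.seeds.to_dict()
        # byte-identical re-serialization
        first = path.read_text()
        pg.save_index(loaded, tmp_path / "idx2")
        assert (tmp_path / "idx2" / "index.json").read_text() == first

    def test_truncated_file_raises(self, rng, tmp_path):
        bundle = self._bundle(rng, n=5)
        path = pg.save_index(bundle, tmp_path / "idx")
        body = path.read_text()
        path.write_text(body[: len(body) // 2])
        with pytest.raises(IndexFormatError):
            pg.load_index(tmp_path / "idx")

    def test_tampered_payload_raises(self, rng, tmp_path):
        bundle = self._bundle(rng, n=5)
        path = pg.save_index(bundle, tmp_path / "idx")
        obj = json.loads(path.read_text())
        obj["payload"]["params"]["k"] = 7
        path.write_text(json.dumps(obj))
        with pytest.raises(IndexFormatError):
            pg.load_index(tmp_path / "idx")

    def test_version_mismatch_raises(self, rng, tmp_path):
        import hashlib

        bundle = self._bundle(rng, n=5)
        path = pg.save_index(bundle, tmp_path / "idx")
        obj = json.loads(path.read_text())
        obj["payload"]["format_version"] = 999
        body = json.dumps(obj["payload"], sort_keys=True, separators=(",", ":"))
        obj["checksum"] = hashlib.sha256(body.encode()).hexdigest()
        path.write_text(json.dumps(obj, sort_keys=True, separators=(",", ":")))
        with pytest.raises(IndexFormatError, match="version"):
            pg.load_index(tmp_path / "idx")
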