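import math

import numpy as np
import pytest

from vmstrack.cleaning import WarningCode
from vmstrack.vms_io import (ConfigError, LoaderConfig, load_config, load_pings,
                             parse_dms, read_logbook, read_vms, save_config,
                             save_pings, store_load, store_save, utc)
from vmstrack.vms_io import LogbookRecord, SCHEMA_VERSION

from conftest import make_ping

VMS_CFG = LoaderConfig(column_map={"vessel_id": "vessel", "timestamp": "datetime",
                                   "lon": "lon", "lat": "lat",
                                   "speed": "speed", "heading": "heading"})
LOG_CFG = LoaderConfig(column_map={"vessel_id": "vessel", "departure": "departure",
                                   "arrival": "arrival", "species": "species",
                                   "quantity": "kg"})


def write(tmp_path, text, name="in.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadVms:
    def test_clean_rows_parse_with_zero_tally(self, tmp_path):
        p = write(tmp_path, "vessel,datetime,lon,lat,speed,heading\n"
                            "V1,2012-06-01 10:00:00,9.5,43.0,4.0,90\n"
                            "V1,2012-06-01 12:00:00,9.4,43.0,4.0,90\n"
                            "V2,2012-06-01 10:00:00,9.0,42.5,10.0,180\n")
        pings, rep = read_vms(p, VMS_CFG)
        assert len(pings) == 3
        assert rep.rows_in == 3 and rep.emitted == 3 and rep.rejected == 0
        assert not rep.counts
        assert [q.vessel_id for q in pings] == ["V1", "V1", "V2"]  # order kept

    def test_out_of_range_latitude_flagged_not_dropped(self, tmp_path):
        p = write(tmp_path, "vessel,datetime,lon,lat,speed,heading\n"
                            "V1,2012-06-01 10:00:00,9.5,95.0,4.0,90\n")
        pings, rep = read_vms(p, VMS_CFG)
        assert len(pings) == 1
        assert WarningCode.OUT_OF_RANGE in pings[0].flags
        assert rep.counts["latitudes out of range (-90/90)"] == 1

    def test_dms_coordinates(self, tmp_path):
        cfg = LoaderConfig(column_map=dict(VMS_CFG.column_map), coord_format="dms")
        p = write(tmp_path, "vessel,datetime,lon,lat,speed,heading\n"
                            "V1,2012-06-01 10:00:00,12°29′46″E,41°54′10″N,4.0,90\n")
        pings, rep = read_vms(p, cfg)
        assert pings[0].lat == pytest.approx(41.9028, abs=1e-4)
        assert pings[0].lon == pytest.approx(12.4961, abs=1e-4)

    def test_bad_timestamp_rejected_and_counts_reconcile(self, tmp_path):
        p = write(tmp_path, "vessel,datetime,lon,lat,speed,heading\n"
                            "V1,not-a-date,9.5,43.0,4.0,90\n"
                            "V1,2012-06-01 12:00:00,bogus,43.0,4.0,90\n"
                            "V1,2012-06-01 14:00:00,9.5,43.0,,90\n")
        pings, rep = read_vms(p, VMS_CFG)
        assert rep.rows_in == rep.emitted + rep.rejected == 3
        assert rep.rejected == 2
        assert math.isnan(pings[0].speed)
        assert rep.counts["NAs found in knots speed"] == 1

    def test_unmapped_mandatory_column_is_config_error(self, tmp_path):
        p = write(tmp_path, "a,b\n1,2\n")
        with pytest.raises(ConfigError):
            read_vms(p, LoaderConfig(column_map={"vessel_id": "a"}))

    def test_empty_file_is_empty_sequence(self, tmp_path):
        pings, rep = read_vms(write(tmp_path, ""), VMS_CFG)
        assert pings == [] and rep.rows_in == 0

    def test_tacsat2_preset_concatenates_date_and_time(self, tmp_path):
        cfg = LoaderConfig.preset("TACSAT2")
        p = write(tmp_path, "VE_REF,SI_LATI,SI_LONG,SI_DATE,SI_TIME,SI_SP,SI_HE\n"
                            "IT001,43.0,9.5,01/06/2012,10:30,4.0,90\n")
        pings, rep = read_vms(p, cfg)
        assert pings[0].timestamp == utc(2012, 6, 1, 10, 30)


def test_parse_dms_hand_conversion():
    # 41 + 54/60 + 10/3600 = 41.902777...
    assert parse_dms("41°54′10″N") == pytest.approx(41 + 54 / 60 + 10 / 3600)
    assert parse_dms("41°54′10″S") == pytest.approx(-(41 + 54 / 60 + 10 / 3600))
    assert math.isnan(parse_dms("garbage"))


class TestReadLogbook:
    def test_pivot_two_species_rows_to_one_trip(self, tmp_path):
        p = write(tmp_path, "vessel,departure,arrival,species,kg\n"
                            "V1,2012-06-01 05:00:00,2012-06-02 06:00:00,HKE,10\n"
                            "V1,2012-06-01 05:00:00,2012-06-02 06:00:00,MUT,5\n")
        recs, rep = read_logbook(p, LOG_CFG)
        assert len(recs) == 1
        assert recs[0].catches == {"HKE": 10.0, "MUT": 5.0}

    def test_repeated_species_summed(self, tmp_path):
        p = write(tmp_path, "vessel,departure,arrival,species,kg\n"
                            "V1,2012-06-01 05:00:00,2012-06-02 06:00:00,HKE,10\n"
                            "V1,2012-06-01 05:00:00,2012-06-02 06:00:00,HKE,7\n")
        recs, _ = read_logbook(p, LOG_CFG)
        assert recs[0].catches == {"HKE": 17.0}

    def test_missing_times_and_inverted_intervals_rejected(self, tmp_path):
        p = write(tmp_path, "vessel,departure,arrival,species,kg\n"
                            "V1,,2012-06-02 06:00:00,HKE,10\n"
                            "V1,2012-06-03 05:00:00,2012-06-02 06:00:00,HKE,10\n"
                            "V1,2012-06-01 05:00:00,2012-06-02 06:00:00,hake,10\n"
                            "V1,2012-06-01 05:00:00,2012-06-02 06:00:00,HKE,10\n")
        recs, rep = read_logbook(p, LOG_CFG)
        assert len(recs) == 1
        assert rep.counts["missing start/end times"] == 1
        assert rep.counts["arrival not after departure"] == 1
        assert rep.counts["invalid species codes"] == 1
        assert rep.rows_in == rep.emitted + rep.rejected

    def test_pivot_conserves_total_catch_mass(self, tmp_path, rng):
        rows = ["vessel,departure,arrival,species,kg"]
        total = 0.0
        for i in range(200):
            v = f"V{rng.integers(3)}"
            d = 1 + int(rng.integers(20))
            sp = rng.choice(["HKE", "MUT", "DPS", "ANE"])
            kg = float(rng.uniform(1, 50))
            total += kg
            rows.append(f"{v},2012-06-{d:02d} 05:00:00,2012-06-{d:02d} 20:00:00,{sp},{kg}")
        recs, rep = read_logbook(write(tmp_path, "\n".join(rows)), LOG_CFG)
        assert sum(sum(r.catches.values()) for r in recs) == pytest.approx(total)


class TestConfigRoundTrip:
    @pytest.mark.parametrize("cfg", [
        VMS_CFG,
        LoaderConfig.preset("TACSAT2"),
        LoaderConfig.preset("EFLALO"),
        LoaderConfig(column_map={"vessel_id": "a", "timestamp": "b", "lon": "c",
                                 "lat": "d", "speed": "e", "heading": "f"},
                     sep="\t", datetime_format="%d/%m/%Y %H:%M",
                     coord_format="dms", dialect="custom"),
    ])
    def test_save_load_is_identity(self, tmp_path, cfg):
        save_config(cfg, tmp_path / "c.cfg")
        assert load_config(tmp_path / "c.cfg") == cfg


class TestStore:
    def _random_pings(self, rng, n=1000):
        pings = []
        codes = list(WarningCode)
        for i in range(n):
            p = make_ping(vessel=f"V{int(rng.integers(5))}",
                          ts=utc(2012, 6, 1 + int(rng.integers(20)), int(rng.integers(24))),
                          lon=float(rng.uniform(8, 10)), lat=float(rng.uniform(42, 44)),
                          speed=float(rng.uniform(0, 12)), heading=float(rng.uniform(0, 360)))
            for c in rng.choice(codes, size=int(rng.integers(0, 3)), replace=False):
                p.flags.add(c)
            if rng.random() < 0.3:
                p.depth = float(-rng.uniform(10, 500))
            if rng.random() < 0.3:
                p.track_id = int(rng.integers(100))
            if rng.random() < 0.2:
                p.is_fishing = bool(rng.random() < 0.5)
            pings.append(p)
        return pings

    def test_ping_round_trip_field_for_field(self, tmp_path, rng):
        pings = self._random_pings(rng)
        store_save(pings, tmp_path / "s.db")
        back = store_load(tmp_path / "s.db")
        assert back == pings

    def test_empty_collection(self, tmp_path):
        store_save([], tmp_path / "s.db")
        assert store_load(tmp_path / "s.db") == []

    def test_vessel_query_returns_subset(self, tmp_path, rng):
        pings = self._random_pings(rng, 200)
        save_pings(pings, tmp_path / "s.db")
        sub = load_pings(tmp_path / "s.db", vessel_id="V2")
        assert sub == [p for p in pings if p.vessel_id == "V2"]

    def test_logbook_round_trip(self, tmp_path):
        recs = [LogbookRecord("V1", utc(2012, 6, 1, 5), utc(2012, 6, 2, 6),
                              {"HKE": 10.0, "MUT": 5.5}, gear="OTB", metier=None)]
        store_save(recs, tmp_path / "s.db")
        assert store_load(tmp_path / "s.db", kind="logbook") == recs

    def test_schema_version_mismatch_names_versions(self, tmp_path):
        import sqlite3

        save_pings([make_ping()], tmp_path / "s.db")
        con = sqlite3.connect(tmp_path / "s.db")
        con.execute("UPDATE meta SET value='999' WHERE key='schema_version'")
        con.commit()
        con.close()
        with pytest.raises(ValueError, match=f"999.*{SCHEMA_VERSION}"):
            load_pings(tmp_path / "s.db")
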