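"""Model construction: architecture table, PCSA arithmetic, strand layout,
bilateral symmetry, and the attachment-coordinate file round trip."""

import numpy as np
import pytest

from jawsim.anatomy import (ALL_PARTS, CLOSER_PARTS, ModelConfig,
                            allocate_strands, build_model, compute_pcsa,
                            load_architecture_table, load_attachments,
                            max_muscle_force, write_attachments)
from jawsim.errors import ConfigError, InvalidParameterError, SchemaError


@pytest.mark.parametrize("mass, flen, pen, rho, expected", [
    (0.3, 0.7, 0.0, 1.05, 0.40816),   # posterior deep masseter row
    (0.5, 0.8, 0.0, 1.05, 0.59524),   # ant. zygomaticomandibularis row
    (2.0, 0.8, 90.0, 1.05, 0.0),      # full pennation: zero projected area
])
def test_pcsa_formula(mass, flen, pen, rho, expected):
    assert compute_pcsa(mass, flen, pen, rho) == pytest.approx(expected, abs=1e-4)


def test_pcsa_rejects_degenerate_inputs():
    with pytest.raises(InvalidParameterError):
        compute_pcsa(1.0, 0.0)
    with pytest.raises(InvalidParameterError):
        compute_pcsa(1.0, 0.7, density=0.0)


def test_max_force_is_pcsa_times_stress():
    assert max_muscle_force(2.436, 25.0) == pytest.approx(60.9)
    assert max_muscle_force(0.0, 25.0) == 0.0
    assert max_muscle_force(1.0, 25.0) == 25.0
    with pytest.raises(InvalidParameterError):
        max_muscle_force(-1.0, 25.0)


def test_architecture_table_internally_consistent_rows():
    """mass/(rho*l) reproduces the tabulated PCSA for the four rows where
    the table is self-consistent (the temporalis and pterygoid rows carry
    provenance metadata only)."""
    df = load_architecture_table().set_index("muscle")
    for name in ("superficial masseter", "posterior deep masseter",
                 "ant. zygomaticomandibularis", "post. zygomaticomandibularis"):
        row = df.loc[name]
        pcsa = compute_pcsa(row["mass_g"], row["fibre_length_cm"])
        assert pcsa == pytest.approx(row["pcsa_cm2"], abs=0.05)


def test_default_model_strand_counts(default_model):
    assert len(default_model.strands) == 150
    for side in ("left", "right"):
        assert sum(1 for s in default_model.strands if s.side == side) == 75


def test_per_muscle_strand_shares_sum_to_architecture_forces(default_model):
    expected = {"medial_pterygoid": 62.3, "superficial_masseter": 60.9,
                "superficial_temporalis": 6.2, "deep_temporalis": 30.9,
                "lateral_pterygoid": 9.8}
    for name, force in expected.items():
        for side in ("left", "right"):
            assert default_model.muscle_max_force(name, side) == \
                pytest.approx(force, rel=1e-9)


def test_total_closer_force(default_model):
    per_side = sum(s.max_force_share for s in default_model.closer_strands
                   if s.side == "right")
    assert per_side == pytest.approx(205.9, rel=1e-9)
    assert default_model.total_closer_force == pytest.approx(411.8, rel=1e-9)


def test_bilateral_mirror_symmetry(default_model):
    """Every right-side strand has an exact mirror image on the left."""
    left = {}
    for s in default_model.strands:
        if s.side == "left":
            left.setdefault(s.muscle, []).append(s)
    for s in default_model.strands:
        if s.side != "right":
            continue
        mirrored = s.points * np.array([1.0, -1.0, 1.0])
        assert any(np.allclose(mirrored, t.points, atol=0.0)
                   for t in left[s.muscle]), s.muscle
    for site in ("molar", "premolar"):
        r = default_model.bite_points[f"{site}_right"]
        l = default_model.bite_points[f"{site}_left"]
        assert np.allclose(r * np.array([1, -1, 1]), l)


def test_model_build_is_deterministic():
    a = build_model()
    b = build_model()
    for sa, sb in zip(a.strands, b.strands):
        assert np.array_equal(sa.points, sb.points)
        assert sa.max_force_share == sb.max_force_share


def test_strand_allocation_rules():
    alloc = allocate_strands({"a": 100.0, "b": 1.0, "c": 1.0}, total=20,
                             min_per_muscle=3, remainder_to="a")
    assert sum(alloc.values()) == 20
    assert alloc["b"] == 3 and alloc["c"] == 3
    with pytest.raises(ConfigError):
        allocate_strands({"a": 1.0, "b": 1.0}, total=4, min_per_muscle=3)


def test_explicit_allocation_must_sum_to_budget():
    bad = {name: 1 for name in ALL_PARTS}
    with pytest.raises(ConfigError):
        build_model(ModelConfig(strand_allocation=bad))


def test_attachment_file_round_trip(tmp_path, default_model):
    path = tmp_path / "attachments.csv"
    write_attachments(default_model, path)
    paths = load_attachments(path)
    assert len(paths) == 150
    for s in default_model.strands[:10]:
        key = next(k for k, (pts, _f) in paths.items()
                   if k[0] == s.muscle and k[1] == s.side
                   and np.array_equal(pts, s.points))
        assert paths[key][1] == s.frames


def test_model_from_attachment_file_matches_synthetic(tmp_path, default_model):
    path = tmp_path / "attachments.csv"
    write_attachments(default_model, path)
    rebuilt = build_model(ModelConfig(geometry_source=str(path)))
    assert len(rebuilt.strands) == 150
    assert rebuilt.total_closer_force == pytest.approx(411.8, rel=1e-9)


def test_attachment_schema_errors(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("muscle,side,strand,role,frame,x,y,z,ordinal\n"
                    "not_a_muscle,right,0,origin,cranium,0,0,0,0\n")
    with pytest.raises(SchemaError, match="unknown muscle"):
        load_attachments(path)
    path.write_text("muscle,side,strand,role,frame,x,y,z,ordinal\n"
                    "digastric,right,0,origin,nowhere,0,0,0,0\n")
    with pytest.raises(SchemaError, match="unknown frame"):
        load_attachments(path)
    path.write_text("muscle,side,role,frame,x,y,z\n")
    with pytest.raises(SchemaError, match="missing columns"):
        load_attachments(path)


def test_via_point_on_digastric_is_kept(tmp_path):
    """A via point on any muscle, digastric included, stays in the path."""
    rows = ["muscle,side,strand,role,frame,x,y,z,ordinal"]
    for side, ysign in (("right", -1), ("left", 1)):
        for part in ALL_PARTS:
            rows.append(f"{part},{side},0,origin,cranium,0,{5*ysign},5,0")
            if part == "digastric":
                rows.append(f"{part},{side},0,via,cranium,10,{5*ysign},-10,1")
            rows.append(f"{part},{side},0,insertion,mandible,20,{5*ysign},-5,2")
    path = tmp_path / "via.csv"
    path.write_text("\n".join(rows) + "\n")
    paths = load_attachments(path)
    pts, frames = paths[("digastric", "right", 0)]
    assert pts.shape == (3, 3)
    assert frames == ("cranium", "cranium", "mandible")


def test_jitter_breaks_symmetry_reproducibly():
    cfg = ModelConfig(symmetric=False, jitter_mm=0.5, seed=7)
    a, b = build_model(cfg), build_model(cfg)
    for sa, sb in zip(a.strands, b.strands):
        assert np.array_equal(sa.points, sb.points)
    right = next(s for s in a.strands if s.side == "right")
    mirrored = right.points * np.array([1, -1, 1])
    partners = [s for s in a.strands
                if s.muscle == right.muscle and s.side == "left"]
    assert not any(np.allclose(mirrored, s.points) for s in partners)
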