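import numpy as np
import pytest

from intarch import clms, docking, synthetic
from intarch.clms import CrosslinkCSM, deduplicate_links, build_restraints
from intarch.docking import (
    DockingError,
    iterative_refine,
    local_refine,
    sample_poses,
    score_pose,
)
from intarch.structures import (
    Assembly,
    AssemblyComponent,
    RigidTransform,
)

from .conftest import ca_structure, random_transform


def two_body_assembly(rec_coords, mob_coords, mob_transform=None):
    rec = ca_structure(rec_coords, id="rec", chain="A")
    mob = ca_structure(mob_coords, id="mob", chain="B")
    return Assembly(
        [
            AssemblyComponent("REC", rec, RigidTransform.identity(), "receptor"),
            AssemblyComponent("MOB", mob, mob_transform or RigidTransform.identity(), "mobile"),
        ]
    )


def restraints_for(assembly, pairs, **kwargs):
    csms = [
        CrosslinkCSM("REC", ("K", a), "MOB", ("K", b), 5.0) for a, b in pairs
    ]
    restraints, _ = build_restraints(
        deduplicate_links(csms), assembly, {"REC": "A", "MOB": "B"}, **kwargs
    )
    return restraints


@pytest.fixture(scope="module")
def docking_case():
    """Toy complex with noiseless links, shared by the docking tests."""
    scenario = synthetic.Scenario(seed=11, receptor_size=60, mobile_size=40)
    receptor, mobile, truth = synthetic.make_toy_complex(scenario)
    csms = synthetic.simulate_crosslinks(truth, 15, decoy_fraction=0.0, seed=11)
    links = deduplicate_links(csms)
    restraints, _ = build_restraints(links, truth, synthetic.CHAIN_MAP)
    return receptor, mobile, truth, restraints


class TestScorePose:
    def test_zero_when_satisfied_and_clash_free(self):
        rec = [[i * 8.0, 0, 0] for i in range(5)]
        mob = [[i * 8.0, 10.0, 0] for i in range(5)]
        asm = two_body_assembly(rec, mob)
        restraints = restraints_for(asm, [(1, 1), (3, 3)])
        pose = score_pose(asm, restraints)
        assert pose.score_total == 0.0
        assert pose.satisfaction == 1.0

    def test_single_restraint_quadratic_echo(self):
        rec = [[0.0, 0, 0], [50.0, 0, 0]]
        mob = [[13.4, 0, 0], [60.0, 0, 0]]  # restraint distance target + 2
        asm = two_body_assembly(rec, mob)
        restraints = restraints_for(asm, [(1, 1)])
        pose = score_pose(asm, restraints)
        assert pose.score_restraint == pytest.approx(4.0)

    def test_score_breakdown_sums(self, docking_case):
        _, _, truth, restraints = docking_case
        pose = score_pose(truth, restraints)
        assert pose.score_total == pose.score_restraint + pose.score_clash

    def test_true_pose_beats_random(self, docking_case):
        _, _, truth, restraints = docking_case
        true_score = score_pose(truth, restraints).score_total
        rng = np.random.default_rng(0)
        for _ in range(100):
            asm = truth.with_transform("MOB", random_transform(rng))
            assert score_pose(asm, restraints).score_total >= true_score

    def test_invariant_under_joint_rigid_transform(self, docking_case):
        _, _, truth, restraints = docking_case
        base = score_pose(truth, restraints)
        rng = np.random.default_rng(3)
        g = random_transform(rng)
        moved = Assembly(
            [
                AssemblyComponent(c.label, c.structure, g.compose(c.transform), c.role)
                for c in truth.components
            ]
        )
        joint = score_pose(moved, restraints)
        assert joint.score_total == pytest.approx(base.score_total, rel=1e-9, abs=1e-9)
        assert joint.satisfaction == base.satisfaction

    def test_empty_restraints_rejected(self, docking_case):
        _, _, truth, _ = docking_case
        with pytest.raises(DockingError):
            score_pose(truth, [])


class TestLocalRefine:
    def test_already_at_minimum_unchanged_score(self):
        rec = [[i * 8.0, 0, 0] for i in range(5)]
        mob = [[i * 8.0, 10.0, 0] for i in range(5)]
        asm = two_body_assembly(rec, mob)
        restraints = restraints_for(asm, [(1, 1), (5, 5)])
        start = score_pose(asm, restraints)
        refined = local_refine(asm, start, restraints, max_evals=300)
        assert refined.score_total <= start.score_total
        assert refined.score_total == pytest.approx(0.0, abs=1e-12)

    def test_never_worse_than_input(self, docking_case):
        receptor, mobile, truth, restraints = docking_case
        rng = np.random.default_rng(4)
        for _ in range(3):
            asm = truth.with_transform("MOB", random_transform(rng))
            start = score_pose(asm, restraints)
            refined = local_refine(asm, start, restraints, max_evals=150)
            assert refined.score_total <= start.score_total + 1e-9

    def test_displaced_pose_recovers_basin(self, docking_case):
        receptor, mobile, truth, restraints = docking_case
        true_T = truth["MOB"].transform
        displaced = RigidTransform(true_T.rotation, true_T.translation + [2.0, 1.5, 1.5])
        asm = truth.with_transform("MOB", displaced)
        start = score_pose(asm, restraints)
        refined = local_refine(asm, start, restraints, max_evals=800, mode="matched")
        mob_ca = mobile.ca_coords()
        rmsd_start = np.sqrt(
            np.mean(np.sum((displaced.apply(mob_ca) - true_T.apply(mob_ca)) ** 2, axis=1))
        )
        rmsd = np.sqrt(
            np.mean(np.sum((refined.transform.apply(mob_ca) - true_T.apply(mob_ca)) ** 2, axis=1))
        )
        # the matched-energy minimum sits within the link-noise scale of truth
        assert rmsd < min(3.0, rmsd_start)

    def test_deterministic(self, docking_case):
        receptor, mobile, truth, restraints = docking_case
        rng = np.random.default_rng(8)
        asm = truth.with_transform("MOB", random_transform(rng))
        start = score_pose(asm, restraints)
        a = local_refine(asm, start, restraints, max_evals=200)
        b = local_refine(asm, start, restraints, max_evals=200)
        np.testing.assert_array_equal(a.transform.rotation, b.transform.rotation)
        assert a.score_total == b.score_total


class TestSamplePoses:
    def test_determinism_bit_identical(self, docking_case):
        receptor, mobile, _, restraints = docking_case
        a = sample_poses(receptor, mobile, restraints, n_starts=2, seed=5, refine_evals=60)
        b = sample_poses(receptor, mobile, restraints, n_starts=2, seed=5, refine_evals=60)
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.transform.rotation, pb.transform.rotation)
            np.testing.assert_array_equal(pa.transform.translation, pb.transform.translation)
            assert pa.score_total == pb.score_total

    def test_ranked_by_score(self, docking_case):
        receptor, mobile, _, restraints = docking_case
        poses = sample_poses(receptor, mobile, restraints, n_starts=8, seed=1, refine_evals=80)
        scores = [p.score_total for p in poses]
        assert scores == sorted(scores)

    def test_dedup_leaves_distinct_poses(self, docking_case):
        receptor, mobile, _, restraints = docking_case
        poses = sample_poses(receptor, mobile, restraints, n_starts=12, seed=2, refine_evals=80)
        mob_ca = mobile.ca_coords()
        coords = [p.transform.apply(mob_ca) for p in poses]
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                rmsd = np.sqrt(np.mean(np.sum((coords[i] - coords[j]) ** 2, axis=1)))
                assert rmsd >= 2.0

    def test_zero_restraints_rejected(self, docking_case):
        receptor, mobile, _, _ = docking_case
        with pytest.raises(DockingError):
            sample_poses(receptor, mobile, [], n_starts=2)


class TestIterativeRefine:
    def test_noiseless_truth_converges_fast(self, docking_case):
        _, _, truth, restraints = docking_case
        start = score_pose(truth, restraints)
        result = iterative_refine(truth, start, restraints)
        assert result.stop_reason == "converged_satisfaction"
        assert result.satisfaction == 1.0
        assert result.n_iterations <= 2

    def test_single_far_decoy_converges_19_of_20(self, docking_case):
        receptor, mobile, truth, _ = docking_case
        csms = synthetic.simulate_crosslinks(truth, 19, decoy_fraction=0.0, seed=23)
        links = deduplicate_links(csms)
        true_r, _ = build_restraints(links, truth, synthetic.CHAIN_MAP)
        # one decoy demanding proximity between sites actually far apart
        rec_xyz = receptor.ca_coords()
        mob_xyz = truth["MOB"].transform.apply(mobile.ca_coords())
        dmat = np.linalg.norm(rec_xyz[:, None, :] - mob_xyz[None, :, :], axis=2)
        i, j = np.unravel_index(np.argmax(dmat), dmat.shape)
        assert dmat[i, j] > 30.0
        decoy = clms.DistanceRestraint(
            site_a=("A", int(i) + 1), site_b=("B", int(j) + 1),
            target=11.4, upper_bound=30.0,
        )
        all_r = true_r + [decoy]
        start = score_pose(truth, all_r)
        result = iterative_refine(truth, start, all_r)
        assert result.satisfaction >= 0.95  # 19/20

    def test_contradictory_restraints_hit_max_iterations(self):
        rec = [[0.0, 0, 0], [100.0, 0, 0]] + [[i * 7.0, 30, 0] for i in range(4)]
        mob = [[0.0, 0, 0], [3.8, 0, 0]]
        asm = two_body_assembly(rec, mob)
        # both mobile residues demanded at receptor sites 100 Å apart
        restraints = restraints_for(asm, [(1, 1), (2, 2), (2, 1)])
        restraints = [r for r in restraints if r.site_a[1] in (1, 2)]
        start = score_pose(asm, restraints)
        result = iterative_refine(
            asm, start, restraints, satisfaction_threshold=1.0, max_iterations=6
        )
        assert result.stop_reason == "max_iterations"

    def test_stop_reason_invariant(self, docking_case):
        _, _, truth, restraints = docking_case
        start = score_pose(truth, restraints)
        result = iterative_refine(truth, start, restraints, satisfaction_threshold=0.90)
        if result.stop_reason == "converged_satisfaction":
            assert result.satisfaction > 0.90

    def test_reproducible(self, docking_case):
        _, _, truth, restraints = docking_case
        start = score_pose(truth, restraints)
        r1 = iterative_refine(truth, start, restraints)
        r2 = iterative_refine(truth, start, restraints)
        assert r1.to_dict()["pose"] == r2.to_dict()["pose"]
        assert r1.restraint_distances == r2.restraint_distances

    def test_saxs_gate_reports_chi2(self, docking_case):
        _, _, truth, restraints = docking_case
        s = np.linspace(0.01, 0.3, 40)
        curve = synthetic.simulate_saxs(truth, s, 0.02, seed=1)
        start = score_pose(truth, restraints)
        result = iterative_refine(truth, start, restraints, saxs_target=curve)
        assert result.saxs_chi2 is not None
        assert result.saxs_chi2 < 5.0  # started at truth, must stay near it
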