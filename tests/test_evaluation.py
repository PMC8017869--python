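import warnings

import numpy as np
import pytest

from hierfs.encoding import Cohort
from hierfs.evaluation import (EvalPlan, evaluate, select_on_cohort,
                               split_permutations)
from hierfs.ilp import SelectionConfig
from hierfs.synthetic import SimSpec, generate, load_generated


@pytest.fixture(scope="module")
def toy_inputs(tmp_path_factory):
    spec = SimSpec(n_samples=60, n_genes=4, n_go_terms=3, seed=11)
    data = generate(spec, tmp_path_factory.mktemp("fixtures"))
    return load_generated(data), data


class TestSplitPermutations:
    def cohort(self, n=10):
        return Cohort([f"S{i}" for i in range(n)],
                      np.array([0, 1] * (n // 2)))

    def test_split_arithmetic_and_disjointness(self):
        plan = EvalPlan(holdout_fraction=0.3, permutations=1)
        (train, hold), = split_permutations(self.cohort(), plan)
        assert len(train) == 7 and len(hold) == 3
        assert not set(train) & set(hold)
        assert set(train) | set(hold) == set(self.cohort().sample_ids)

    def test_permutations_differ(self):
        plan = EvalPlan(permutations=10, seed=5)
        splits = split_permutations(self.cohort(20), plan)
        holdouts = {tuple(sorted(h)) for _, h in splits}
        assert len(holdouts) > 1

    def test_stratification_keeps_both_classes(self):
        plan = EvalPlan(holdout_fraction=0.3, permutations=5)
        cohort = self.cohort(20)
        for train, _ in split_permutations(cohort, plan):
            labels = cohort.subset(train).labels
            assert set(labels.tolist()) == {0, 1}

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            EvalPlan(holdout_fraction=0.0)


class TestEvaluate:
    def test_separable_cohort_reaches_auc_one(self, toy_inputs):
        (structure, variants, cohort), data = toy_inputs
        # noise-free labels equal to the planted node's vector
        clean = Cohort(cohort.sample_ids,
                       np.array(data.truth["carriers"], dtype=int))
        plan = EvalPlan(permutations=2, seed=0)
        df, _ = evaluate(structure, variants, clean, "ilp", plan,
                         sel_config=SelectionConfig(t=0.1), compute_cv=False)
        assert (df["holdout_auc"] == 1.0).all()

    def test_shuffled_labels_give_null_auc(self, toy_inputs):
        (structure, variants, cohort), _ = toy_inputs
        rng = np.random.default_rng(7)
        null = Cohort(cohort.sample_ids, rng.permutation(cohort.labels))
        plan = EvalPlan(permutations=10, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df, _ = evaluate(structure, variants, null, "threshold", plan,
                             sel_config=SelectionConfig(t=0.0), compute_cv=False)
        assert 0.35 <= df["holdout_auc"].mean() <= 0.65

    def test_same_seed_reproduces_auc_table(self, toy_inputs):
        (structure, variants, cohort), _ = toy_inputs
        plan = EvalPlan(permutations=2, seed=3)
        df1, s1 = evaluate(structure, variants, cohort, "ilp", plan,
                           sel_config=SelectionConfig(t=0.1), compute_cv=False)
        df2, s2 = evaluate(structure, variants, cohort, "ilp", plan,
                           sel_config=SelectionConfig(t=0.1), compute_cv=False)
        assert df1.equals(df2) and s1 == s2

    def test_empty_selection_records_half_auc(self, toy_inputs):
        (structure, variants, cohort), _ = toy_inputs
        plan = EvalPlan(permutations=1, seed=0)
        with pytest.warns(UserWarning, match="empty"):
            df, _ = evaluate(structure, variants, cohort, "ilp", plan,
                             sel_config=SelectionConfig(t=5.0), compute_cv=False)
        assert df["holdout_auc"].iloc[0] == 0.5

    def test_relieff_not_available(self, toy_inputs):
        (structure, variants, cohort), _ = toy_inputs
        with pytest.raises(NotImplementedError):
            select_on_cohort(structure, variants, cohort, "relieff-topc",
                             SelectionConfig())

    def test_unknown_selector_rejected(self, toy_inputs):
        (structure, variants, cohort), _ = toy_inputs
        with pytest.raises(ValueError, match="selector"):
            select_on_cohort(structure, variants, cohort, "boosting",
                             SelectionConfig())


def strip_holdout_from_files(data, keep, out_dir):
    """Rewrite the VCF and label files with only ``keep`` samples."""
    import shutil
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    keep = list(keep)
    lines = Path(data.vcf).read_text().splitlines()
    new = []
    cols = None
    for line in lines:
        if line.startswith("##"):
            new.append(line)
        elif line.startswith("#CHROM"):
            parts = line.split("\t")
            cols = [9 + parts[9:].index(s) for s in keep]
            new.append("\t".join(parts[:9] + keep))
        else:
            parts = line.split("\t")
            new.append("\t".join(parts[:9] + [parts[c] for c in cols]))
    (out / "cohort.vcf").write_text("\n".join(new) + "\n")
    labels = dict(l.split("\t") for l in Path(data.labels).read_text().splitlines())
    (out / "labels.tsv").write_text("".join(f"{s}\t{labels[s]}\n" for s in keep))
    for name in ("gff3", "obo", "gaf"):
        shutil.copy(getattr(data, name), out / Path(getattr(data, name)).name)
    from hierfs.synthetic import GeneratedData
    return GeneratedData(vcf=out / "cohort.vcf", gff3=out / Path(data.gff3).name,
                         obo=out / Path(data.obo).name, gaf=out / Path(data.gaf).name,
                         labels=out / "labels.tsv", truth=data.truth)


class TestLeakage:
    def test_deleting_holdout_rows_leaves_selection_identical(self, toy_inputs, tmp_path):
        """The training-side selection must not change when holdout
        samples are physically removed from every input file."""
        from hierfs.evaluation import _subset_variants
        (structure, variants, cohort), data = toy_inputs
        plan = EvalPlan(permutations=1, seed=9)
        (train, _hold), = split_permutations(cohort, plan)
        tidx = np.array([cohort.sample_ids.index(s) for s in train])

        full_side, _, _, _ = select_on_cohort(
            structure, _subset_variants(variants, tidx), cohort.subset(train),
            "ilp", SelectionConfig(t=0.1))

        reduced = strip_holdout_from_files(data, train, tmp_path / "reduced")
        structure2, variants2, cohort2 = load_generated(reduced)
        deleted_side, _, _, _ = select_on_cohort(
            structure2, variants2, cohort2, "ilp", SelectionConfig(t=0.1))
        assert sorted(full_side) == sorted(deleted_side)
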