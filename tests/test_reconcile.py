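"""Discretization, CPT learning and exact decorated-tree inference."""

import numpy as np
import pytest

from helpers import (enumerate_posteriors, random_model, random_scores,
                     random_tree)
from ontoweave.base_learner import ScoreTable
from ontoweave.gold_standard import GenePair, PairLabelSet
from ontoweave.ontology import InteractionOntology, Term
from ontoweave.reconcile import (DiscretizationScheme, HierarchicalModel,
                                 ObservationCPT, StructuralCPT,
                                 fit_discretizer, infer_posteriors,
                                 learn_observation_cpt, learn_structural_cpts,
                                 load_model, map_assignment, save_model)


def gp(a, b, ordered=False):
    return GenePair(a, b, ordered=ordered)


def score_table(term, values):
    pairs = [gp(f"a{i}", f"b{i}") for i in range(len(values))]
    return ScoreTable(term, pairs, np.asarray(values, dtype=float))


class TestDiscretizer:
    def test_mean_falls_in_middle_bin(self, rng):
        d = fit_discretizer(score_table("t", rng.normal(2.0, 1.0, 500)))
        assert int(d.bin_index(d.mean)) == d.n_bins // 2

    def test_far_outlier_clipped_to_end_bins(self, rng):
        d = fit_discretizer(score_table("t", rng.normal(0, 1, 200)))
        assert int(d.bin_index(d.mean + 100 * d.sd)) == d.n_bins - 1
        assert int(d.bin_index(d.mean - 100 * d.sd)) == 0

    def test_bin_counts_match_independent_histogram(self, rng):
        vals = rng.uniform(-4, 4, 1000)
        d = fit_discretizer(score_table("t", vals))
        ours = np.bincount(d.bin_index(vals), minlength=d.n_bins)
        clipped = np.clip(vals, d.edges[0], d.edges[-1])
        ref, _ = np.histogram(clipped, bins=d.edges)
        # np.histogram puts the top edge in the last bin, as we do
        assert np.array_equal(ours, ref)

    def test_zero_variance_single_bin(self):
        d = fit_discretizer(score_table("t", [1.0, 1.0, 1.0]))
        assert d.n_bins == 1
        assert int(d.bin_index(123.0)) == 0

    def test_span_is_five_sds_each_side(self, rng):
        d = fit_discretizer(score_table("t", rng.normal(0, 2, 300)))
        assert d.edges[0] == pytest.approx(d.mean - 5 * d.sd)
        assert d.edges[-1] == pytest.approx(d.mean + 5 * d.sd)


class TestObservationCPT:
    def test_laplace_formula(self):
        # 2 bins; positives with bin counts (3, 1), alpha=1 -> (4/6, 2/6)
        d = DiscretizationScheme("t", 0.5, 0.5, 2, np.array([0.0, 0.5, 1.0]))
        pos = [gp(f"p{i}", f"q{i}") for i in range(4)]
        neg = [gp(f"n{i}", f"m{i}") for i in range(2)]
        labels = PairLabelSet("t", set(pos), set(neg))
        scores = ScoreTable("t", pos + neg,
                            np.array([0.1, 0.2, 0.3, 0.7, 0.1, 0.9]))
        cpt = learn_observation_cpt(scores, labels, d, pseudocount=1.0)
        assert np.allclose(cpt.table[1], [4 / 6, 2 / 6])
        assert np.allclose(cpt.table[0], [2 / 4, 2 / 4])

    def test_matches_counting_oracle(self, rng):
        d = DiscretizationScheme("t", 0.0, 1.0, 5, np.linspace(-5, 5, 6))
        pos = [gp(f"p{i}", f"q{i}") for i in range(40)]
        neg = [gp(f"n{i}", f"m{i}") for i in range(30)]
        labels = PairLabelSet("t", set(pos), set(neg))
        vals = rng.uniform(-6, 6, 70)
        scores = ScoreTable("t", pos + neg, vals)
        a = 1.0
        cpt = learn_observation_cpt(scores, labels, d, a)
        lookup = scores.as_dict()
        for x, group in ((1, pos), (0, neg)):
            counts = np.zeros(5)
            for p in group:
                counts[int(d.bin_index(lookup[p]))] += 1
            assert np.allclose(cpt.table[x], (counts + a) / (len(group) + a * 5))

    def test_rows_normalized_and_positive(self, rng):
        d = DiscretizationScheme("t", 0.0, 1.0, 10, np.linspace(-5, 5, 11))
        pos = [gp(f"p{i}", f"q{i}") for i in range(10)]
        neg = [gp(f"n{i}", f"m{i}") for i in range(10)]
        labels = PairLabelSet("t", set(pos), set(neg))
        scores = ScoreTable("t", pos + neg, rng.normal(size=20))
        cpt = learn_observation_cpt(scores, labels, d)
        assert np.allclose(cpt.table.sum(axis=1), 1.0)
        assert (cpt.table > 0).all()


class TestStructuralCPT:
    def _chain(self):
        return InteractionOntology({
            "root": Term("root"),
            "mid": Term("mid", parent="root"),
            "leaf": Term("leaf", parent="mid"),
        })

    def test_counts_match_conditional_frequency_oracle(self, rng):
        o = self._chain()
        genes = [f"g{i}" for i in range(30)]
        leaf_pos = set()
        for _ in range(25):
            a, b = rng.choice(30, size=2, replace=False)
            leaf_pos.add(gp(genes[a], genes[b]))
        mid_extra = set()
        for _ in range(10):
            a, b = rng.choice(30, size=2, replace=False)
            mid_extra.add(gp(genes[a], genes[b]))
        mid_pos = leaf_pos | mid_extra
        root_pos = set(mid_pos)
        def negs(pos, n):
            out = set()
            while len(out) < n:
                a, b = rng.choice(30, size=2, replace=False)
                p = gp(genes[a], genes[b])
                if p not in pos:
                    out.add(p)
            return out
        labels = {
            "leaf": PairLabelSet("leaf", leaf_pos, negs(leaf_pos, 25)),
            "mid": PairLabelSet("mid", mid_pos, negs(mid_pos, 35)),
            "root": PairLabelSet("root", root_pos, negs(root_pos, 35)),
        }
        cpts = learn_structural_cpts(o, labels, pseudocount=1.0)
        # oracle for "mid": pairs of mid's standard negative at leaf
        leaf_keys = {p.genes for p in leaf_pos}
        all_off = [p for p in labels["mid"].labeled_pairs()
                   if p.genes not in leaf_keys]
        n_on = sum(1 for p in all_off if p.genes in {q.genes for q in mid_pos})
        assert cpts["mid"].p_all_off == pytest.approx(
            (n_on + 1) / (len(all_off) + 2))
        # leaf prior oracle
        assert cpts["leaf"].prior == pytest.approx((25 + 1) / (50 + 2))
        assert cpts["leaf"].children == ()
        assert cpts["root"].children == ("mid",)

    def test_every_parent_positive_has_positive_child(self):
        o = self._chain()
        pos = {gp("a", "b"), gp("c", "d")}
        labels = {t: PairLabelSet(t, set(pos), {gp("e", "f")}) for t in o.terms}
        cpts = learn_structural_cpts(o, labels, pseudocount=1.0)
        # no parent-positive pair lacks a positive child: numerator is pure
        # pseudocount over the all-off pairs (here only the shared negative)
        assert cpts["mid"].p_all_off == pytest.approx(1 / 3)

    def test_hierarchy_violation_detected(self):
        o = self._chain()
        labels = {
            "root": PairLabelSet("root", {gp("a", "b")}, {gp("c", "d")}),
            "mid": PairLabelSet("mid", {gp("a", "b")}, {gp("c", "d")}),
            "leaf": PairLabelSet("leaf", {gp("x", "y")}, {gp("c", "d")}),
        }
        with pytest.raises(ValueError, match="violate hierarchy"):
            learn_structural_cpts(o, labels)


class TestInference:
    def test_single_term_bayes_rule(self):
        o = InteractionOntology({"root": Term("root")})
        d = DiscretizationScheme("root", 0.0, 1.0, 2, np.array([-5.0, 0.0, 5.0]))
        # likelihood ratio 3 in the top bin, prior 0.5
        obs = ObservationCPT("root", np.array([[0.75, 0.25], [0.25, 0.75]]))
        struct = StructuralCPT("root", (), prior=0.5)
        m = HierarchicalModel(o, {"root": d}, {"root": obs}, {"root": struct})
        scores = {"root": ScoreTable("root", [gp("a", "b")], np.array([2.0]))}
        post = infer_posteriors(m, scores)
        assert post.posterior[0, 0] == pytest.approx(0.75)

    def test_chain_parent_posterior_dominates_child(self, rng):
        for _ in range(20):
            o = random_tree(int(rng.integers(2, 8)), rng)
            m = random_model(o, rng)
            post = infer_posteriors(m, random_scores(m, rng, gp("a", "b")))
            vals = dict(zip(post.terms, post.posterior[0]))
            for t in o.terms:
                for c in o.children[t]:
                    assert vals[t] >= vals[c] - 1e-9

    def test_marginals_match_enumeration(self, rng):
        for _ in range(40):
            o = random_tree(int(rng.integers(1, 11)), rng)
            m = random_model(o, rng)
            scores = random_scores(m, rng, gp("a", "b"))
            bins = {t: int(m.discretizers[t].bin_index(scores[t].scores[0]))
                    for t in o.terms}
            post = infer_posteriors(m, scores)
            ref = enumerate_posteriors(m, bins)
            assert np.allclose(post.posterior[0], ref, atol=1e-9)

    def test_uninformative_evidence_returns_prior(self, rng):
        for _ in range(10):
            o = random_tree(int(rng.integers(1, 9)), rng)
            m = random_model(o, rng)
            for t in o.terms:  # make evidence carry no information
                m.observation[t].table[1] = m.observation[t].table[0]
            scores = random_scores(m, rng, gp("a", "b"))
            bins = {t: 0 for t in o.terms}
            post = infer_posteriors(m, scores)
            prior = enumerate_posteriors(m, bins)  # evidence cancels in oracle
            assert np.allclose(post.posterior[0], prior, atol=1e-9)

    def test_stronger_evidence_never_decreases_posterior(self, rng):
        o = random_tree(6, rng)
        m = random_model(o, rng)
        target = list(o.terms)[3]
        scores = random_scores(m, rng, gp("a", "b"))
        # sweep the target term's likelihood ratio upward, all else fixed
        b = int(m.discretizers[target].bin_index(scores[target].scores[0]))
        last = -1.0
        for lr in [0.25, 0.5, 1.0, 2.0, 4.0, 8.0]:
            tab = np.full((2, m.observation[target].n_bins), 1.0)
            tab[1, b] = lr
            tab /= tab.sum(axis=1, keepdims=True)
            m.observation[target] = ObservationCPT(target, tab)
            post = infer_posteriors(m, scores)
            val = post.posterior[0, post.terms.index(target)]
            assert val >= last - 1e-12
            last = val

    def test_missing_scores_policy(self, rng):
        o = random_tree(4, rng)
        m = random_model(o, rng)
        scores = random_scores(m, rng, gp("a", "b"))
        dropped = list(o.terms)[2]
        partial = {t: s for t, s in scores.items() if t != dropped}
        with pytest.raises(KeyError, match=dropped):
            infer_posteriors(m, partial, on_missing="error")
        post = infer_posteriors(m, partial, on_missing="marginalize")
        bins = {t: int(m.discretizers[t].bin_index(scores[t].scores[0]))
                for t in o.terms}
        # oracle: neutral likelihood for the dropped term
        m.observation[dropped].table[:] = 1.0 / m.observation[dropped].n_bins
        ref = enumerate_posteriors(m, bins)
        assert np.allclose(post.posterior[0], ref, atol=1e-9)

    def test_map_assignment_is_upward_closed_and_most_probable(self, rng):
        import itertools
        for _ in range(15):
            o = random_tree(int(rng.integers(1, 7)), rng)
            m = random_model(o, rng)
            scores = random_scores(m, rng, gp("a", "b"))
            bins = {t: int(m.discretizers[t].bin_index(scores[t].scores[0]))
                    for t in o.terms}
            states = map_assignment(m, scores)
            vals = dict(zip(states.terms, states.posterior[0].astype(int)))
            for t in o.terms:  # consistency: on child forces on parent
                for c in o.children[t]:
                    assert vals[t] >= vals[c]
            # oracle: exhaustive joint maximization
            terms = m.terms
            best, best_p = None, -1.0
            for assign in itertools.product([0, 1], repeat=len(terms)):
                x = dict(zip(terms, assign))
                p = 1.0
                for t in terms:
                    s = m.structure[t]
                    if s.children:
                        p1 = 1.0 if any(x[c] for c in s.children) else s.p_all_off
                    else:
                        p1 = s.prior
                    p *= p1 if x[t] else 1 - p1
                    p *= m.observation[t].table[x[t], bins[t]]
                if p > best_p:
                    best, best_p = x, p
            joint_ours = 1.0
            for t in terms:
                s = m.structure[t]
                if s.children:
                    p1 = 1.0 if any(vals[c] for c in s.children) else s.p_all_off
                else:
                    p1 = s.prior
                joint_ours *= p1 if vals[t] else 1 - p1
                joint_ours *= m.observation[t].table[vals[t], bins[t]]
            assert joint_ours == pytest.approx(best_p)


class TestPredictPipeline:
    def _world(self, directed_fraction, seed):
        from ontoweave.base_learner import cross_val_scores, train_bagged
        from ontoweave.reconcile import fit_hierarchical_model, predict_pipeline
        from ontoweave.synth import (SynthConfig, make_features, make_ontology,
                                     plant_labels)
        cfg = SynthConfig(n_genes=120, positive_rate=0.02, depth=1, branching=2,
                          directed_fraction=directed_fraction, seed=seed)
        o = make_ontology(cfg)
        labels = plant_labels(o, cfg)
        feats = make_features(o, labels, cfg)
        classifiers, train_scores = {}, {}
        for i, t in enumerate(o.topological_order()):
            ft = feats.featurize(labels[t].labeled_pairs(), term=t)
            classifiers[t] = train_bagged(ft, labels[t], n_members=3, seed=i)
            train_scores[t] = cross_val_scores(ft, labels[t], n_members=3, seed=i)
        model = fit_hierarchical_model(o, train_scores, labels)
        return o, labels, feats, classifiers, model

    def test_composition_matches_manual_steps(self, rng):
        from ontoweave.base_learner import predict_scores
        from ontoweave.reconcile import infer_posteriors, predict_pipeline
        o, labels, feats, classifiers, model = self._world(0.0, seed=21)
        pairs = sorted(labels[o.root].positives, key=lambda p: (p.a, p.b))[:10]
        features = {t: feats.featurize(pairs, term=t) for t in o.terms}
        auto = predict_pipeline(model, classifiers, features, pairs=pairs)
        manual_scores = {t: predict_scores(classifiers[t], features[t])
                         for t in o.terms}
        manual = infer_posteriors(model, manual_scores, pairs=pairs)
        assert np.allclose(auto.posterior, manual.posterior, atol=0)
        # evidence pushes positives of the root above its implied prior
        # (prior = posterior with every observation marginalized out)
        prior = infer_posteriors(model, {}, pairs=pairs, on_missing="marginalize")
        assert auto.posterior[:, auto.terms.index(o.root)].mean() > \
            prior.posterior[:, prior.terms.index(o.root)].mean()

    def test_orientation_symmetry_on_undirected_ontology(self, rng):
        from ontoweave.reconcile import predict_pipeline
        o, labels, feats, classifiers, model = self._world(0.0, seed=22)
        base = sorted(labels[o.root].positives, key=lambda p: (p.a, p.b))[:8]
        fwd = [GenePair(p.a, p.b, ordered=True) for p in base]
        rev = [p.flipped() for p in fwd]
        post_f = predict_pipeline(model, classifiers,
                                  {t: feats.featurize(fwd, term=t) for t in o.terms},
                                  pairs=fwd)
        post_r = predict_pipeline(model, classifiers,
                                  {t: feats.featurize(rev, term=t) for t in o.terms},
                                  pairs=rev)
        assert np.allclose(post_f.posterior, post_r.posterior, atol=0)

    def test_map_mode_returns_binary_assignments(self, rng):
        from ontoweave.reconcile import predict_pipeline
        o, labels, feats, classifiers, model = self._world(0.0, seed=23)
        pairs = labels[o.root].labeled_pairs()[:12]
        features = {t: feats.featurize(pairs, term=t) for t in o.terms}
        states = predict_pipeline(model, classifiers, features, pairs=pairs,
                                  mode="map")
        assert set(np.unique(states.posterior)) <= {0.0, 1.0}


def test_model_bundle_roundtrip(tmp_path, rng):
    o = random_tree(5, rng)
    m = random_model(o, rng)
    save_model(m, tmp_path / "bundle")
    back = load_model(tmp_path / "bundle")
    scores = random_scores(m, rng, gp("a", "b"))
    a = infer_posteriors(m, scores).posterior
    b = infer_posteriors(back, scores).posterior
    assert np.allclose(a, b, atol=0)
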