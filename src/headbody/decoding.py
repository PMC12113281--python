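"""Pseudo-population decoding of head-body angle and avatar orientation.

Non-simultaneously recorded units are combined into pseudo-population
vectors: per stimulus, each unit's 8 trials are independently permuted and
stacked, yielding 8 population vectors per stimulus.  A linear support
vector classifier (C = 1) is trained with eightfold cross-validation whose
folds are *orientation balanced*: every fold trains on 7 trials per
orientation per class (56 per class with 8 orientations, 28 with 4) and
tests on 1 trial per orientation per class.  Because both classes of an
angle contrast contain the identical multisets of head and of body
orientations, the classifier can only exploit the head-body *conjunction*;
a guard rejects any unbalanced class construction, and a deliberately
confounded fold scheme is provided to demonstrate the below-chance
artifacts that unbalanced folds produce.

Chance levels come from permutation nulls: the stimulus labels of the
pseudo-population vectors are shuffled (within each centering source) and
the identical pipeline is rerun, by default 200 times; figures-style bands
are the min-max of the run means.

Variants: cross-centering generalization (train MC, test HC or vice
versa), cross-orientation generalization (train the '+' orientations, test
the 'x' orientations), decoding from summed isolated head + body net
responses, 8-way orientation decoding (upright versus inverted), and a
neuron-dropping contribution analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .screening import net_rates, response_rates
from .simulate import UnitRecording
from .stimuli import (
    ORIENTATIONS,
    PLUS_ORIENTATIONS,
    StimulusCondition,
    monkey_condition,
)

N_TRIALS = 8


class BalanceError(ValueError):
    """Raised when an angle contrast's classes are not orientation balanced."""


@dataclass
class DecodingResult:
    """Per-resampling test accuracies for one decoding contrast."""

    accuracies: np.ndarray
    n_classes: int = 2
    null_accuracies: Optional[np.ndarray] = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0

    @property
    def chance(self) -> float:
        return 1.0 / self.n_classes

    @property
    def null_band(self) -> Tuple[float, float]:
        if self.null_accuracies is None:
            raise ValueError("no permutation null attached")
        return float(np.min(self.null_accuracies)), float(np.max(self.null_accuracies))

    def exceeds_null(self) -> bool:
        """Mean accuracy above the null band's upper edge."""
        return self.mean > self.null_band[1]

    def within_null(self) -> bool:
        lo, hi = self.null_band
        return lo <= self.mean <= hi


def check_balance(class_conditions: Mapping[object, Sequence[Tuple[int, int]]]) -> None:
    """Verify that all classes share the same multisets of head and of body
    orientations; raises :class:`BalanceError` otherwise.

    ``class_conditions`` maps class label to a sequence of
    ``(head_orientation, body_orientation)`` pairs.
    """
    ref_h = ref_b = None
    for label, pairs in class_conditions.items():
        heads = sorted(h for h, _ in pairs)
        bodies = sorted(b for _, b in pairs)
        if ref_h is None:
            ref_h, ref_b = heads, bodies
        elif heads != ref_h or bodies != ref_b:
            raise BalanceError(
                f"class {label!r} has head/body orientation multisets "
                f"{heads}/{bodies} differing from {ref_h}/{ref_b}"
            )


def _rate_matrix(units: Sequence[UnitRecording], cond: StimulusCondition,
                 kind: str) -> np.ndarray:
    """(n_trials, n_units) raw or net response rates for one condition."""
    fn = response_rates if kind == "raw" else net_rates
    cols = []
    for u in units:
        if cond not in u.counts:
            raise ValueError(f"unit {u.unit_id} lacks condition {cond}")
        r = fn(u, cond)
        if len(r) != N_TRIALS:
            raise ValueError(f"unit {u.unit_id} has {len(r)} trials, need {N_TRIALS}")
        cols.append(r)
    return np.stack(cols, axis=1)


def _permute_columns(mat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each unit's trials (one column per unit)."""
    n_t, n_u = mat.shape
    idx = rng.permuted(np.broadcast_to(np.arange(n_t), (n_u, n_t)).copy(), axis=1)
    return mat[idx.T, np.arange(n_u)]


@dataclass(frozen=True)
class PseudoPopulation:
    """Per-stimulus pseudo-population vectors (8 per stimulus)."""

    vectors: Mapping[StimulusCondition, np.ndarray]
    unit_ids: Tuple[str, ...]
    subjects: Tuple[str, ...]


def build_pseudopopulation(
    units: Sequence[UnitRecording],
    conditions: Sequence[StimulusCondition],
    response_kind: str = "raw",
    seed: int | np.random.Generator = 0,
) -> PseudoPopulation:
    """Assemble 8 pseudo-population vectors per stimulus by independently
    permuting each unit's trial order."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vectors = {
        c: _permute_columns(_rate_matrix(units, c, response_kind), rng)
        for c in conditions
    }
    return PseudoPopulation(
        vectors=vectors,
        unit_ids=tuple(u.unit_id for u in units),
        subjects=tuple(u.subject for u in units),
    )


def balanced_folds(
    class_conditions: Mapping[object, Sequence[object]],
    n_trials: int = N_TRIALS,
    seed: int | np.random.Generator = 0,
) -> List[Dict[object, Tuple[np.ndarray, int]]]:
    """Eightfold balanced cross-validation plan.

    For every condition a random permutation of its trial slots is drawn;
    fold ``k`` holds out slot ``perm[k]`` of each condition for testing and
    trains on the remaining ``n_trials - 1`` slots.  Each fold therefore
    trains on 7 trials per orientation per class and every trial is tested
    exactly once.  Returns, per fold, ``{cond: (train_slots, test_slot)}``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conds: List[object] = []
    for cs in class_conditions.values():
        conds.extend(cs)
    perms = {c: rng.permutation(n_trials) for c in conds}
    folds = []
    for k in range(n_trials):
        folds.append({
            c: (np.delete(perms[c], k), int(perms[c][k])) for c in conds
        })
    return folds


def _fit_predict(X_train, y_train, X_test, first_label) -> np.ndarray:
    # iteration cap guards against libsvm's pathological iteration counts on
    # chance-level (non-separable) data; solutions on signal-bearing data
    # converge far earlier
    try:
        clf = SVC(kernel="linear", C=1.0, max_iter=3000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X_train, y_train)
        return clf.predict(X_test)
    except ValueError:
        return np.full(len(X_test), first_label)


def _slot_fold_accuracy(train_classes, test_classes, vecs, rng,
                        fold_groups=None) -> float:
    """Mean test accuracy over the eightfold balanced slot CV.

    ``fold_groups`` maps condition keys to a shared group id: keys in one
    group use the same slot permutation, so conditions composed from the
    same underlying trials (e.g. head-body sums of the two angle classes
    sharing one isolated-body recording) never place a trial in one
    class's training set and the other's test set.
    """
    all_keys = []
    for cs in train_classes.values():
        all_keys.extend(cs)
    for cs in test_classes.values():
        for c in cs:
            if c not in all_keys:
                all_keys.append(c)
    if fold_groups is None:
        fold_groups = {c: c for c in all_keys}
    group_perms = {g: rng.permutation(N_TRIALS)
                   for g in dict.fromkeys(fold_groups[c] for c in all_keys)}
    perms = {c: group_perms[fold_groups[c]] for c in all_keys}
    labels = sorted(train_classes)
    first = labels[0]
    correct = total = 0
    accs = []
    for k in range(N_TRIALS):
        X_tr, y_tr = [], []
        for label, cs in train_classes.items():
            for c in cs:
                X_tr.append(vecs[c][np.delete(perms[c], k)])
                y_tr.extend([label] * (N_TRIALS - 1))
        X_te, y_te = [], []
        for label, cs in test_classes.items():
            for c in cs:
                X_te.append(vecs[c][perms[c][k]][None, :])
                y_te.append(label)
        pred = _fit_predict(np.vstack(X_tr), np.array(y_tr), np.vstack(X_te), first)
        accs.append(np.mean(pred == np.array(y_te)))
    return float(np.mean(accs))


def _confounded_fold_accuracy(classes, vecs, rng) -> float:
    """Deliberately orientation-confounded folds (artifact demonstration).

    Per fold, each class holds out *all* trials of one orientation for
    testing and trains on the other orientations' trials -- with the two
    classes holding out different orientations, so the training sets are
    orientation unbalanced between classes.
    """
    labels = sorted(classes)
    n_or = len(classes[labels[0]])
    base_perm = rng.permutation(n_or)
    held = {label: np.roll(base_perm, i) for i, label in enumerate(labels)}
    first = labels[0]
    accs = []
    for k in range(n_or):
        X_tr, y_tr, X_te, y_te = [], [], [], []
        for label in labels:
            conds = classes[label]
            test_cond = conds[held[label][k]]
            for c in conds:
                if c is test_cond:
                    X_te.append(vecs[c])
                    y_te.extend([label] * N_TRIALS)
                else:
                    X_tr.append(vecs[c])
                    y_tr.extend([label] * N_TRIALS)
        pred = _fit_predict(np.vstack(X_tr), np.array(y_tr), np.vstack(X_te), first)
        accs.append(np.mean(pred == np.array(y_te)))
    return float(np.mean(accs))


def _shuffle_labels(vecs: Dict[object, np.ndarray], source_of: Mapping[object, object],
                    rng: np.random.Generator) -> Dict[object, np.ndarray]:
    """Permute vectors across the condition/slot grid within each source."""
    out = dict(vecs)
    by_source: Dict[object, List[object]] = {}
    for key, src in source_of.items():
        by_source.setdefault(src, []).append(key)
    for keys in by_source.values():
        pool = np.vstack([vecs[c] for c in keys])
        pool = pool[rng.permutation(len(pool))]
        for i, c in enumerate(keys):
            out[c] = pool[i * N_TRIALS:(i + 1) * N_TRIALS]
    return out


def _subsample_units(subjects: Sequence[str], n_units: Optional[int],
                     rng: np.random.Generator,
                     allowed: Optional[Sequence[int]] = None) -> np.ndarray:
    if allowed is None:
        allowed = range(len(subjects))
    if n_units is None:
        return np.asarray(list(allowed))
    groups: Dict[str, List[int]] = {}
    for i in allowed:
        groups.setdefault(subjects[i], []).append(i)
    per = n_units // len(groups)
    if per * len(groups) != n_units:
        raise ValueError("n_units must divide evenly across subjects")
    idx = []
    for s in sorted(groups):
        g = groups[s]
        if len(g) < per:
            raise ValueError(f"subject {s} has only {len(g)} units, need {per}")
        idx.extend(rng.choice(g, size=per, replace=False))
    return np.array(idx)


def _decode_core(
    component_pool: Mapping[object, np.ndarray],
    components: Mapping[object, Sequence[object]],
    source_of: Mapping[object, object],
    train_classes: Mapping[object, Sequence[object]],
    test_classes: Mapping[object, Sequence[object]],
    subjects: Sequence[str],
    n_units: Optional[int],
    n_resamples: int,
    seed: int,
    permute_labels: bool,
    fold_scheme: str,
    fold_groups: Optional[Mapping[object, object]] = None,
    stream: int = 0,
    allowed: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Shared resampling engine.

    ``component_pool`` holds (8, n_all_units) trial-rate matrices of the
    underlying recordings; ``components[key]`` lists the pool entries whose
    per-unit-permuted *sum* yields condition ``key``'s pseudo-population
    vectors.  Each pool entry is permuted once per resampling, so two
    conditions built from the same recording stay slot-aligned (see
    ``fold_groups``).  Per resampling: draw units (subject balanced, shared
    across compared contrasts through the seed), permute trials, optionally
    shuffle the stimulus labels, then run the fold scheme.

    Trial permutations are keyed by full-roster column and component (not
    by sequential RNG consumption), so analyses on unit subsets -- the
    neuron-dropping leave-one-out in particular -- reuse exactly the same
    trial assembly as the full roster and differ only in the units present.
    """
    accs = np.empty(n_resamples)
    for i in range(n_resamples):
        rng = np.random.default_rng([seed, stream, i])
        idx = _subsample_units(subjects, n_units, rng, allowed)
        permuted = {}
        for ci, (cid, m) in enumerate(component_pool.items()):
            u = np.random.default_rng([seed, stream, i, 7919 + ci]).random(m.shape)
            perm = np.argsort(u, axis=0)
            permuted[cid] = np.take_along_axis(m, perm, axis=0)[:, idx]
        vecs = {key: sum(permuted[cid] for cid in comps)
                for key, comps in components.items()}
        if permute_labels:
            vecs = _shuffle_labels(vecs, source_of, rng)
        if fold_scheme == "slot":
            accs[i] = _slot_fold_accuracy(train_classes, test_classes, vecs, rng,
                                          fold_groups)
        elif fold_scheme == "orientation_confounded":
            accs[i] = _confounded_fold_accuracy(train_classes, vecs, rng)
        else:
            raise ValueError(f"unknown fold scheme {fold_scheme!r}")
    return accs


def decode_angle_pair(
    units: Sequence[UnitRecording],
    angles: Tuple[int, int] = (0, 180),
    pose: str = "P1",
    train_centering: str = "MC",
    test_centering: Optional[str] = None,
    train_orientations: Sequence[int] = ORIENTATIONS,
    test_orientations: Optional[Sequence[int]] = None,
    inversion: str = "upright",
    response_kind: str = "raw",
    n_units: Optional[int] = None,
    n_resamples: int = 100,
    seed: int = 0,
    permute_labels: bool = False,
    fold_scheme: str = "slot",
    exclude_unit_ids: Sequence[str] = (),
) -> DecodingResult:
    """Pooled-orientation decoding of one head-body angle pair.

    Both classes pool the given avatar orientations, so only the head-body
    conjunction separates them; a balance guard enforces this.  Set
    ``test_centering`` for cross-centering generalization and
    ``test_orientations`` for cross-orientation ('+' vs 'x')
    generalization.
    """
    test_centering = test_centering or train_centering
    test_orientations = (train_orientations if test_orientations is None
                         else test_orientations)
    train_classes, test_classes = {}, {}
    for a in angles:
        train_classes[a] = [monkey_condition(pose, b, a, train_centering, inversion)
                            for b in train_orientations]
        test_classes[a] = [monkey_condition(pose, b, a, test_centering, inversion)
                           for b in test_orientations]
    for classes in (train_classes, test_classes):
        check_balance({
            lab: [(c.head_orientation, c.body_orientation) for c in cs]
            for lab, cs in classes.items()
        })
    # deterministic key order: dict/set iteration feeds the RNG consumption
    # order, so it must not depend on the per-process hash seed
    keys: List[StimulusCondition] = []
    for cs in list(train_classes.values()) + list(test_classes.values()):
        for c in cs:
            if c not in keys:
                keys.append(c)
    pool = {c: _rate_matrix(units, c, response_kind) for c in keys}
    components = {c: [c] for c in keys}
    source_of = {c: c.centering for c in keys}
    excluded = set(exclude_unit_ids)
    allowed = [i for i, u in enumerate(units) if u.unit_id not in excluded] \
        if excluded else None
    accs = _decode_core(
        pool, components, source_of, train_classes, test_classes,
        [u.subject for u in units], n_units, n_resamples, seed,
        permute_labels, fold_scheme, allowed=allowed,
    )
    return DecodingResult(accuracies=accs, n_classes=len(angles))


def decode_from_sums(
    units: Sequence[UnitRecording],
    angles: Tuple[int, int] = (0, 180),
    pose: str = "P1",
    centering: str = "MC",
    orientations: Sequence[int] = PLUS_ORIENTATIONS,
    n_units: Optional[int] = None,
    n_resamples: int = 100,
    seed: int = 0,
    permute_labels: bool = False,
) -> DecodingResult:
    """Angle decoding from summed isolated head + body net responses.

    For every (angle, orientation) the matched isolated head and headless
    body trials are independently permuted per unit and summed trial-wise,
    yielding 8 head-body sums per orientation and angle; decoding then
    follows the standard balanced procedure on these sums.
    """
    train_classes: Dict[int, List[object]] = {}
    pool: Dict[object, np.ndarray] = {}
    components: Dict[object, List[object]] = {}
    fold_groups: Dict[object, object] = {}
    pairs: Dict[int, List[Tuple[int, int]]] = {}
    for a in angles:
        train_classes[a] = []
        pairs[a] = []
        for b in orientations:
            h = (b + a) % 360
            head_cond = StimulusCondition(pose=pose, part="head", head_orientation=h,
                                          centering=centering, anchor_orientation=b)
            body_cond = StimulusCondition(pose=pose, part="body", body_orientation=b,
                                          centering=centering)
            for c in (head_cond, body_cond):
                if c not in pool:
                    pool[c] = _rate_matrix(units, c, "net")
            key = ("sum", a, b)
            components[key] = [head_cond, body_cond]
            # angle classes at one orientation share the isolated-body trials:
            # keep their CV slots aligned so shared trials never leak into
            # the other class's training set
            fold_groups[key] = ("orientation", b)
            train_classes[a].append(key)
            pairs[a].append((h, b))
    check_balance(pairs)
    source_of = {key: "sum" for key in components}
    accs = _decode_core(
        pool, components, source_of, train_classes, train_classes,
        [u.subject for u in units], n_units, n_resamples, seed,
        permute_labels, "slot", fold_groups=fold_groups,
    )
    return DecodingResult(accuracies=accs, n_classes=len(angles))


def decode_orientation(
    units: Sequence[UnitRecording],
    pose: str = "P1",
    inversion: str = "upright",
    angle: int = 0,
    centering: str = "MC",
    orientations: Sequence[int] = ORIENTATIONS,
    response_kind: str = "raw",
    n_units: Optional[int] = 60,
    n_resamples: int = 100,
    seed: int = 0,
    permute_labels: bool = False,
) -> DecodingResult:
    """8-way decoding of avatar orientation for one head-body angle.

    Units are redrawn (subject balanced) per resampling; the linear SVC
    handles the multiclass problem with its native one-vs-one scheme.
    """
    classes = {
        b: [monkey_condition(pose, b, angle, centering, inversion)]
        for b in orientations
    }
    keys = [c for cs in classes.values() for c in cs]
    pool = {c: _rate_matrix(units, c, response_kind) for c in keys}
    components = {c: [c] for c in keys}
    source_of = {c: c.centering for c in keys}
    accs = _decode_core(
        pool, components, source_of, classes, classes,
        [u.subject for u in units], n_units, n_resamples, seed,
        permute_labels, "slot",
    )
    return DecodingResult(accuracies=accs, n_classes=len(orientations))


def permutation_null(
    decode_fn: Callable[..., DecodingResult],
    n_runs: int = 200,
    n_resamples: int = 1,
    seed: int = 0,
    **kwargs,
) -> np.ndarray:
    """Null distribution of mean accuracies under stimulus-label permutation.

    Each run permutes the pseudo-population vectors across the contrast's
    condition/slot grid and reruns the identical pipeline; the run's value
    is the mean over ``n_resamples`` resamplings.  Run seeds derive from
    ``seed`` on a separate stream so nulls never reuse the main
    resamplings' randomness.
    """
    out = np.empty(n_runs)
    for run in range(n_runs):
        res = decode_fn(n_resamples=n_resamples,
                        seed=int(np.random.default_rng([seed, 1, run]).integers(2**31)),
                        permute_labels=True, **kwargs)
        out[run] = res.mean
    return out


def decode_with_null(
    decode_fn: Callable[..., DecodingResult],
    n_resamples: int = 100,
    null_runs: int = 200,
    null_resamples: int = 1,
    seed: int = 0,
    **kwargs,
) -> DecodingResult:
    """Run a decoding contrast and attach its permutation-null distribution."""
    res = decode_fn(n_resamples=n_resamples, seed=seed, **kwargs)
    res.null_accuracies = permutation_null(
        decode_fn, n_runs=null_runs, n_resamples=null_resamples, seed=seed, **kwargs
    )
    return res


def compare_decodings(result_a: DecodingResult, result_b: DecodingResult) -> float:
    """Resampling p-value for the paired accuracy difference a - b.

    Both results must share the per-resampling unit draws (same seed and
    roster).  The p-value is the percentile of a zero difference in the
    per-resampling difference distribution; a two-tailed test is
    significant when p < 0.025 or p > 0.975.
    """
    a, b = result_a.accuracies, result_b.accuracies
    if len(a) != len(b):
        raise ValueError("results have different numbers of resamplings")
    d = a - b
    return float((np.sum(d < 0) + 0.5 * np.sum(d == 0)) / len(d))


def inversion_difference(
    upright: DecodingResult, inverted: DecodingResult, block: int = 10
) -> np.ndarray:
    """Distribution of upright - inverted accuracy differences between
    means of ``block`` consecutive resamplings."""
    n = (min(len(upright.accuracies), len(inverted.accuracies)) // block) * block
    if n == 0:
        raise ValueError(f"need at least {block} resamplings")
    up = upright.accuracies[:n].reshape(-1, block).mean(axis=1)
    inv = inverted.accuracies[:n].reshape(-1, block).mean(axis=1)
    return up - inv


def angle_effect_p(unit: UnitRecording, pose: str = "P1", centering: str = "MC",
                   inversion: str = "upright") -> float:
    """One-way ANOVA p-value for the effect of head-body angle on raw
    response rates (orientations pooled within each angle)."""
    from .stimuli import ANGLES

    groups = []
    for a in ANGLES:
        rates = []
        for b in ORIENTATIONS:
            cond = monkey_condition(pose, b, a, centering, inversion)
            if cond in unit.counts:
                rates.append(response_rates(unit, cond))
        if rates:
            groups.append(np.concatenate(rates))
    if len(groups) < 2:
        raise ValueError("need at least two angle groups")
    return float(stats.f_oneway(*groups).pvalue)


@dataclass
class NeuronDroppingResult:
    """Leave-one-out contribution ranking and greedy inclusion curve."""

    unit_ids: List[str]          # ranked, most contributing first
    contributions: np.ndarray    # accuracy drop when the unit is removed
    curve_sizes: List[int]
    curve_accuracies: np.ndarray
    top_units: List[str]

    def top_fraction(self, flags: Mapping[str, bool]) -> float:
        """Fraction of the top units for which ``flags[unit_id]`` is True."""
        return float(np.mean([bool(flags[u]) for u in self.top_units]))


def neuron_dropping(
    units: Sequence[UnitRecording],
    decode_kwargs: Optional[dict] = None,
    n_resamples: int = 10,
    seed: int = 0,
    top_k: int = 10,
    curve_sizes: Optional[Sequence[int]] = None,
) -> NeuronDroppingResult:
    """Rank units by their leave-one-out contribution to a decoding contrast.

    ``contribution = accuracy(all units) - accuracy(all but this unit)``;
    the curve re-decodes with the top-k ranked units for each requested
    roster size.  All decodings share the resampling seed *and* the trial
    assembly (permutations are keyed by full-roster position), so each
    leave-one-out difference isolates the removed unit's effect.
    """
    kwargs = dict(angles=(0, 180))
    kwargs.update(decode_kwargs or {})
    kwargs.update(n_units=None, n_resamples=n_resamples, seed=seed)
    base = decode_angle_pair(units, **kwargs).mean
    contrib = np.empty(len(units))
    for i, unit in enumerate(units):
        contrib[i] = base - decode_angle_pair(
            units, exclude_unit_ids=[unit.unit_id], **kwargs).mean
    order = np.argsort(-contrib)
    ranked_ids = [units[i].unit_id for i in order]
    if curve_sizes is None:
        curve_sizes = sorted({2, 5, 10, len(units)} & set(range(2, len(units) + 1)))
    curve = np.empty(len(curve_sizes))
    for k, size in enumerate(curve_sizes):
        keep = set(ranked_ids[:size])
        curve[k] = decode_angle_pair(
            units, exclude_unit_ids=[u.unit_id for u in units
                                     if u.unit_id not in keep], **kwargs).mean
    return NeuronDroppingResult(
        unit_ids=ranked_ids,
        contributions=contrib[order],
        curve_sizes=list(curve_sizes),
        curve_accuracies=curve,
        top_units=ranked_ids[:top_k],
    )
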