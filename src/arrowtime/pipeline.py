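"""High-level train/score procedures composing the pipeline stages.

These are the library counterparts of the CLI workflow: build balanced
forward/backward pattern sets, train one direction classifier per
condition on a participant-disjoint split, and score the held-out
participants.  For small cohorts, :func:`condition_mean_R` repeats the
split over several shuffles and averages — the standard remedy when a
single 10% hold-out is only a couple of participants.
"""

from __future__ import annotations

import numpy as np

from arrowtime import model as _model
from arrowtime import reversibility as _rev
from arrowtime import windowing as _win


def train_and_score(cohort, w: int, shift: int, seed: int = 0,
                    eval_fraction: float = 0.1,
                    train_config: _model.TrainConfig | None = None,
                    label_randomize: bool = False):
    """One split, one model per condition, traces for held-out participants.

    Returns ``(nets, traces)`` where ``nets`` maps condition to the trained
    classifier and ``traces`` is a list of per-participant
    :class:`~arrowtime.reversibility.ReversibilityTrace`.  With
    ``label_randomize`` the forward/backward labels are shuffled before
    training — the null model in which no direction information is
    learnable by construction.
    """
    split = _win.split_by_participant(
        [s.participant_id for s in cohort], eval_fraction, seed)
    train_cohort = [s for s in cohort
                    if s.participant_id in split.train_participants]
    datasets = _win.build_dataset(train_cohort, "global", w, shift)
    nets = {}
    for (condition, _unit), ps in sorted(datasets.items()):
        y = ps.y
        if label_randomize:
            rng = np.random.default_rng(seed + 104729)
            y = y[rng.permutation(len(y))]
        net = _model.build_net(
            ps.n_regions * ps.w, seed=seed,
            metadata={"scale": "global", "unit": ps.unit,
                      "condition": condition, "w": w, "shift": shift,
                      "train_participants": sorted(split.train_participants),
                      "label_randomized": label_randomize})
        cfg = train_config or _model.TrainConfig(seed=seed)
        _model.train_net(net, ps.X, y, cfg)
        nets[condition] = net
    traces = []
    for s in cohort:
        if s.participant_id not in split.eval_participants:
            continue
        traces.append(_rev.evaluate_trace(nets[s.condition], s, w, shift))
    return nets, traces


def condition_mean_R(cohort, w: int, shift: int, n_shuffles: int = 5,
                     seed: int = 0, eval_fraction: float = 0.1,
                     label_randomize: bool = False) -> float:
    """Shuffle-averaged condition-level mean nonreversibility.

    Repeats :func:`train_and_score` over ``n_shuffles`` independent
    participant splits (seeds ``seed .. seed + n_shuffles - 1``) and
    averages the held-out participants' mean R across all shuffles.  All
    series in ``cohort`` must share one condition.
    """
    conditions = {s.condition for s in cohort}
    if len(conditions) != 1:
        raise ValueError(f"cohort must hold one condition, got {sorted(conditions)}")
    vals = []
    for sh in range(n_shuffles):
        _nets, traces = train_and_score(
            cohort, w, shift, seed=seed + sh, eval_fraction=eval_fraction,
            label_randomize=label_randomize)
        vals.extend(tr.mean_R for tr in traces)
    return float(np.mean(vals))


def heldout_direction_accuracy(net, cohort_eval, w: int, shift: int):
    """Accuracy of the direction classifier on held-out patterns.

    Returns ``(accuracy, n_patterns)`` pooled over the given held-out
    series; each window contributes a forward and a backward pattern.
    """
    correct = 0
    total = 0
    for s in cohort_eval:
        ds = _win.build_dataset([s], "global", w, shift)
        ps = next(iter(ds.values()))
        probs = net.predict_proba(ps.X)
        correct += int(np.sum(probs.argmax(axis=1) == ps.y))
        total += ps.n_patterns
    return correct / total, total
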