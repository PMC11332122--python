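import numpy as np
import pytest

from stargrid.game import (Action, GameConfig, GameLog, GridState, PlayerSpec,
                           TurnRecord)


@pytest.fixture
def mixed_config():
    return GameConfig(seed=3)


@pytest.fixture
def small_state():
    """Hand-built 3-player board used by transition tests."""
    return GridState(
        turn_index=0,
        positions={0: (4, 4), 1: (4, 9), 2: (0, 0)},
        timeout={},
        scores={0: 0, 1: 0, 2: 0},
        stars=[(2, 4)],
    )


def make_record(actor, positions, stars, action, zapped=(), collected=False,
                turn=0):
    return TurnRecord(turn_index=turn, actor_id=actor,
                      positions=dict(positions), stars=list(stars),
                      action=action, zapped_ids=tuple(zapped),
                      star_collected=collected)


@pytest.fixture
def scripted_log():
    """Tiny hand-scripted game: participant 0, bots 1-4, known actions.

    Turn 0: participant shares a row with bot 1 (ingroup zapper) and a
    column with bot 3 (outgroup zapper) and zaps bot 1; bots 2 and 4 are
    off-line.  Turn 1: participant moves while sharing a line with bot 3.
    """
    config = GameConfig(seed=0, n_turns=2)
    stars = [(9, 9)]
    pos0 = {0: (2, 2), 1: (2, 6), 2: (5, 5), 3: (7, 2), 4: (8, 6)}
    recs = [
        make_record(0, pos0, stars, Action("zap", "right"), zapped=(1,), turn=0),
        make_record(2, {k: v for k, v in pos0.items() if k != 1}, stars,
                    Action("move", "up"), turn=0),
        make_record(3, {0: (2, 2), 2: (4, 5), 3: (7, 2), 4: (8, 6)}, stars,
                    Action("move", "up"), turn=0),
        make_record(4, {0: (2, 2), 2: (4, 5), 3: (6, 2), 4: (8, 6)}, stars,
                    Action("move", "right"), turn=0),
        # round 1: bot 1 returns not yet (timeout); participant moves in line
        # with bot 3 (same column after bot 3 moved to (6,2)... keep (6,2))
        make_record(0, {0: (2, 2), 2: (4, 5), 3: (6, 2), 4: (8, 7)}, stars,
                    Action("move", "down"), turn=1),
        make_record(2, {0: (3, 2), 2: (4, 5), 3: (6, 2), 4: (8, 7)}, stars,
                    Action("move", "left"), turn=1),
    ]
    return GameLog(config, recs)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
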