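# Game-log and event-file schemas

## Game log (JSON Lines)

One game per file.  The first line is the config header; every following
line is one turn record.  Coordinates are 0-based `(row, col)`, row-major,
origin at the **top-left**; `up` decreases the row index.

### Header line

```json
{"type": "config", "grid_size": 10, "n_players": 5, "n_turns": 100,
 "star_spawn_prob": 0.75, "star_expire_prob": 0.05, "timeout_turns": 3,
 "n_initial_stars": 5, "ray_stops_at_first": false,
 "grouping": "groups", "behavior": "mixed",
 "players": [{"player_id": 0, "role": "participant", "policy": "model_agent",
              "team": "blue", "relation_to_participant": "self"}, ...],
 "turn_order": [0, 1, 2, 3, 4], "seed": 7}
```

`grouping` ∈ {groups, neutral}; `behavior` ∈ {all_zappers, all_avoiders,
mixed}; `policy` ∈ {zapper, avoider, model_agent, external};
`relation_to_participant` ∈ {self, ingroup, outgroup, neutral}.

### Turn record lines

```json
{"type": "turn", "turn": 12, "actor": 3,
 "positions": {"0": [2, 5], "1": [7, 7], "3": [2, 9], "4": [0, 1]},
 "stars": [[4, 4], [9, 0]],
 "action": {"kind": "move", "direction": "left"},
 "zapped": [], "star_collected": false}
```

* `turn` — 0-based round index; records appear in `turn_order` within a
  round; players inside the time-out zone emit no record.
* `positions` / `stars` — the **pre-move** snapshot (active players only;
  stars in spawn order).  All covariates and classifications derive from
  this snapshot.
* `action.kind` ∈ {move, zap}; `direction` ∈ {up, down, left, right}.
* `zapped` — ids of players caught in the ray (all players on the line
  unless `ray_stops_at_first`); they are absent from `positions` for
  exactly `timeout_turns` subsequent rounds.
* `star_collected` — true iff the move landed on a star (the star is
  removed and the actor's score increments).

## Opportunity-event CSV (`stargrid extract`)

One row per (participant turn, in-line candidate target):

| column            | meaning                                              |
|-------------------|------------------------------------------------------|
| `seq`             | 1-based index of the source record in the log        |
| `turn`            | round index                                          |
| `observer`        | deciding player id (the participant)                 |
| `target`          | candidate target id (shares a row or column)         |
| `relation`        | target's relation to the observer (ingroup/outgroup/neutral) |
| `could_zap`       | always true for emitted rows                         |
| `observed_action` | zap / avoid / none for the observer's act            |
| `chose_zap`       | whether the observer's ray included this target      |
| `star_dist`       | Manhattan distance to the nearest star ÷ `divisor`   |
| `target_dist`     | Manhattan distance to the target ÷ `divisor`         |
| `divisor`         | the scaling divisor used (default 10)                |
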