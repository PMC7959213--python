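# cbloop

A closed-loop simulator of an EEG brain-computer-interface experiment with
deceptive feedback. Synthetic 64-channel EEG carries two phase-opposed
1.875 Hz steady-state responses whose relative gain follows a latent
attentional state; a lagged backward (stimulus-reconstruction) model decodes
the attended item from 3 s windows every 250 ms; end-of-trial feedback is
deliberately wrong on 25% of trials; and a reliability-weighted
cue-integration observer turns internal evidence plus the feedback cue into
reports and 4-level confidence ratings. The analysis layer produces the
headline summary tables (accuracy by feedback type, by confidence split, by
internal-evidence quartile, consistency on deceptive trials) and a
fixed-effects logistic regression of accuracy on internal evidence and
feedback type.

## Layout

| module                  | role                                                    |
|-------------------------|---------------------------------------------------------|
| `cbloop.stimulus`       | abstract 1-D phase-opposed stimulus templates           |
| `cbloop.synth`          | synthetic raw EEG generator + cue-integration observer  |
| `cbloop.preprocess`     | downsample, causal Butterworth band-pass, average ref   |
| `cbloop.decoder`        | backward-model training, scoring, decisions, CV         |
| `cbloop.trial_engine`   | schedules and closed-loop session simulation            |
| `cbloop.metrics`        | internal evidence, consistency, accuracy labels         |
| `cbloop.analysis`       | summary tables, bootstrap CIs, logistic regression      |
| `cbloop.config`         | run configuration, seed derivation, full pipeline       |
| `cbloop.cli`            | `cbloop` command-line entry point                       |

## CLI

All subcommands accept `--config <yaml>` (defaults to the frozen calibrated
configuration), `--seed <int>` and `--out <path>`:

```bash
cbloop simulate     --out sim/                 # training-phase EEG + labels
cbloop train        --out model.json           # fit the backward model
cbloop run-session  --out session.csv          # one closed-loop session
cbloop analyze      --session sessions.csv --out report/
cbloop pipeline     --out run/                 # train -> sessions -> analyze
```

`cbloop pipeline` writes per-participant session CSVs, a combined
`sessions.csv`, four summary tables, the logistic fit, a provenance JSON
(config hash, seeds, library versions) and the resolved config. Reruns with
the same config reproduce every output byte for byte; existing session files
are reused (resume).

## Configuration

`cbloop.config.DEFAULT_CONFIG` holds the frozen calibration: generator SNR
(`noise_sd`) tuned once against the reference training-phase decoding
accuracy, and observer parameters tuned once against the reference report
accuracies, then fixed. Any block can be overridden from YAML; see
`RunConfig.default().to_yaml(...)` for a template.
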