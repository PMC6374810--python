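"""One-call experiment: generate -> train -> predict -> refine -> evaluate.

Everything is driven by an ExperimentConfig (serializable to YAML; the CLI
command ``msdseg run config.yaml`` wraps exactly this function).  A master
seed derives per-stage seeds, so a config file reproduces a run bit for
bit.  Sizes here are desk scale; raise them for a real study.
"""

from msdseg import ExperimentConfig, run_experiment
from msdseg.config import InferenceConfig
from msdseg.levelset import LevelSetConfig
from msdseg.msdensenet import NetworkConfig
from msdseg.phantom import PhantomConfig
from msdseg.training import TrainConfig

cfg = ExperimentConfig(
    out_dir="experiment_out",
    seed=0,
    n_train=2,
    n_test=1,
    phantom=PhantomConfig(),
    network=NetworkConfig(growth_rate=6, initial_channels=8,
                          decoder_compress_channels=48,
                          decoder_up_channels=24, subvolume_size=16),
    train=TrainConfig(max_iterations=150, subvolume_size=16),
    inference=InferenceConfig(patch=16, stride=8),
    levelset=LevelSetConfig(),
)
cfg.to_yaml("experiment.yaml")  # the same run is reproducible from this file

table = run_experiment(cfg)
print(table.to_string(index=False))
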