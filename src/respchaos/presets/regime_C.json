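{
  "pfrg_params": {
    "epsilon": 0.005,
    "beta": 0.4,
    "d": 0.4,
    "a": 0.2,
    "m0": 0.864,
    "m1": 0.65,
    "delta": 0.2,
    "x_th": -0.02,
    "tau1": 10,
    "tau2": 2,
    "J": 0.18
  },
  "prebot_params": {
    "epsilon": 0.005,
    "beta": 0.4,
    "d": 0.4,
    "a": 0.2,
    "m0": 0.864,
    "m1": 0.65,
    "delta": 0.2,
    "x_th": -0.02,
    "tau1": 5,
    "tau2": 10,
    "J": 0.0
  },
  "synapses": [
    {
      "source": "pfrg",
      "target": "prebot",
      "K": 0.1,
      "tau_syn": 5
    },
    {
      "source": "prebot",
      "target": "pfrg",
      "K": -0.3,
      "tau_syn": 5
    }
  ],
  "offswitch_enabled": true,
  "n_steps": 60000,
  "n_transient": 5000,
  "spike_threshold": 0.3
}
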