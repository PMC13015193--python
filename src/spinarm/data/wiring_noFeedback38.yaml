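variant: noFeedback38
parameter_count: 38
neurons:
- FlxAlpha
- ExtAlpha
- FlxPN
- ExtPN
- FlxIaIN
- ExtIaIN
- FlxIbIN
- ExtIbIN
- FlxRenshaw
- ExtRenshaw
- FlxMuscle
- ExtMuscle
afferents: []
synapses:
- pre: FlxPN
  post: FlxAlpha
  sign: excitatory
  max_conductance: 2.0
- pre: ExtPN
  post: ExtAlpha
  sign: excitatory
  max_conductance: 2.0
- pre: FlxAlpha
  post: FlxRenshaw
  sign: excitatory
  max_conductance: 2.0
- pre: ExtAlpha
  post: ExtRenshaw
  sign: excitatory
  max_conductance: 2.0
- pre: FlxRenshaw
  post: FlxAlpha
  sign: inhibitory
  max_conductance: 2.0
- pre: ExtRenshaw
  post: ExtAlpha
  sign: inhibitory
  max_conductance: 2.0
- pre: FlxRenshaw
  post: FlxIaIN
  sign: inhibitory
  max_conductance: 2.0
- pre: ExtRenshaw
  post: ExtIaIN
  sign: inhibitory
  max_conductance: 2.0
- pre: FlxIaIN
  post: ExtAlpha
  sign: inhibitory
  max_conductance: 2.0
- pre: ExtIaIN
  post: FlxAlpha
  sign: inhibitory
  max_conductance: 2.0
- pre: FlxIaIN
  post: ExtIaIN
  sign: inhibitory
  max_conductance: 2.0
- pre: ExtIaIN
  post: FlxIaIN
  sign: inhibitory
  max_conductance: 2.0
- pre: FlxIbIN
  post: FlxAlpha
  sign: inhibitory
  max_conductance: 2.0
- pre: ExtIbIN
  post: ExtAlpha
  sign: inhibitory
  max_conductance: 2.0
- pre: FlxIbIN
  post: ExtAlpha
  sign: inhibitory
  max_conductance: 2.0
- pre: ExtIbIN
  post: FlxAlpha
  sign: inhibitory
  max_conductance: 2.0
- pre: FlxIbIN
  post: ExtIbIN
  sign: inhibitory
  max_conductance: 2.0
- pre: ExtIbIN
  post: FlxIbIN
  sign: inhibitory
  max_conductance: 2.0
- pre: FlxPN
  post: ExtPN
  sign: inhibitory
  max_conductance: 2.0
- pre: ExtPN
  post: FlxPN
  sign: inhibitory
  max_conductance: 2.0
- pre: FlxAlpha
  post: FlxMuscle
  sign: excitatory
  max_conductance: 6.0
- pre: ExtAlpha
  post: ExtMuscle
  sign: excitatory
  max_conductance: 6.0
set_neuron_targets:
- FlxAlpha
- ExtAlpha
- FlxPN
- ExtPN
- FlxIaIN
- ExtIaIN
- FlxIbIN
- ExtIbIN
- FlxRenshaw
- ExtRenshaw
set_synapse_targets:
- - FlxPN
  - FlxAlpha
- - ExtPN
  - ExtAlpha
- - FlxAlpha
  - FlxRenshaw
- - ExtAlpha
  - ExtRenshaw
- - FlxRenshaw
  - FlxAlpha
- - ExtRenshaw
  - ExtAlpha
- - FlxRenshaw
  - FlxIaIN
- - ExtRenshaw
  - ExtIaIN
- - FlxIaIN
  - ExtAlpha
- - ExtIaIN
  - FlxAlpha
- - FlxIaIN
  - ExtIaIN
- - ExtIaIN
  - FlxIaIN
- - FlxIbIN
  - FlxAlpha
- - ExtIbIN
  - ExtAlpha
- - FlxIbIN
  - ExtAlpha
- - ExtIbIN
  - FlxAlpha
- - FlxIbIN
  - ExtIbIN
- - ExtIbIN
  - FlxIbIN
- - FlxPN
  - ExtPN
- - ExtPN
  - FlxPN
go_targets:
- FlxPN
- ExtPN
- FlxIaIN
- ExtIaIN
- FlxIbIN
- ExtIbIN
- FlxRenshaw
- ExtRenshaw
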