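variant: noIb36
parameter_count: 36
neurons:
- FlxAlpha
- ExtAlpha
- FlxGamma
- ExtGamma
- FlxPN
- ExtPN
- FlxIaIN
- ExtIaIN
- FlxRenshaw
- ExtRenshaw
- FlxMuscle
- ExtMuscle
afferents:
- Flx1a
- Ext1a
synapses:
- pre: Flx1a
  post: FlxAlpha
  sign: excitatory
  max_conductance: 2.0
- pre: Ext1a
  post: ExtAlpha
  sign: excitatory
  max_conductance: 2.0
- pre: Flx1a
  post: FlxPN
  sign: excitatory
  max_conductance: 2.0
- pre: Ext1a
  post: ExtPN
  sign: excitatory
  max_conductance: 2.0
- pre: Flx1a
  post: FlxIaIN
  sign: excitatory
  max_conductance: 2.0
- pre: Ext1a
  post: ExtIaIN
  sign: excitatory
  max_conductance: 2.0
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
- FlxGamma
- ExtGamma
- FlxPN
- ExtPN
- FlxIaIN
- ExtIaIN
- FlxRenshaw
- ExtRenshaw
set_synapse_targets:
- - Flx1a
  - FlxAlpha
- - Ext1a
  - ExtAlpha
- - Flx1a
  - FlxPN
- - Ext1a
  - ExtPN
- - Flx1a
  - FlxIaIN
- - Ext1a
  - ExtIaIN
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
- - FlxPN
  - ExtPN
- - ExtPN
  - FlxPN
go_targets:
- FlxPN
- ExtPN
- FlxIaIN
- ExtIaIN
- FlxRenshaw
- ExtRenshaw
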