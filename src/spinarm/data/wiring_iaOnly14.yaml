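variant: iaOnly14
parameter_count: 14
neurons:
- FlxAlpha
- ExtAlpha
- FlxGamma
- ExtGamma
- FlxPN
- ExtPN
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
- pre: FlxPN
  post: FlxAlpha
  sign: excitatory
  max_conductance: 2.0
- pre: ExtPN
  post: ExtAlpha
  sign: excitatory
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
set_synapse_targets:
- - Flx1a
  - FlxAlpha
- - Ext1a
  - ExtAlpha
- - Flx1a
  - FlxPN
- - Ext1a
  - ExtPN
- - FlxPN
  - FlxAlpha
- - ExtPN
  - ExtAlpha
go_targets:
- FlxPN
- ExtPN
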