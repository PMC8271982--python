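{
 "$defs": {
  "PathsConfig": {
   "additionalProperties": false,
   "properties": {
    "data": {
     "default": "data",
     "title": "Data",
     "type": "string"
    },
    "models": {
     "default": "models",
     "title": "Models",
     "type": "string"
    },
    "reports": {
     "default": "reports",
     "title": "Reports",
     "type": "string"
    }
   },
   "title": "PathsConfig",
   "type": "object"
  },
  "ProtocolOverrides": {
   "additionalProperties": false,
   "properties": {
    "n_subjects": {
     "anyOf": [
      {
       "minimum": 1,
       "type": "integer"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "N Subjects"
    },
    "n_frames": {
     "anyOf": [
      {
       "minimum": 32,
       "type": "integer"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "N Frames"
    },
    "sigma": {
     "anyOf": [
      {
       "maximum": 0.02,
       "minimum": 0,
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Sigma"
    }
   },
   "title": "ProtocolOverrides",
   "type": "object"
  },
  "TrainingOverrides": {
   "additionalProperties": false,
   "properties": {
    "epochs": {
     "anyOf": [
      {
       "minimum": 1,
       "type": "integer"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Epochs"
    },
    "batch_size": {
     "anyOf": [
      {
       "minimum": 1,
       "type": "integer"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Batch Size"
    },
    "learning_rate": {
     "anyOf": [
      {
       "exclusiveMinimum": 0,
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Learning Rate"
    },
    "momentum": {
     "anyOf": [
      {
       "exclusiveMaximum": 1,
       "minimum": 0,
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Momentum"
    },
    "weight_decay": {
     "anyOf": [
      {
       "minimum": 0,
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Weight Decay"
    },
    "runs": {
     "anyOf": [
      {
       "minimum": 1,
       "type": "integer"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Runs"
    }
   },
   "title": "TrainingOverrides",
   "type": "object"
  }
 },
 "additionalProperties": false,
 "properties": {
  "paths": {
   "$ref": "#/$defs/PathsConfig",
   "default": {
    "data": "data",
    "models": "models",
    "reports": "reports"
   }
  },
  "ordering": {
   "default": "B1",
   "title": "Ordering",
   "type": "string"
  },
  "window_length": {
   "default": 32,
   "minimum": 1,
   "title": "Window Length",
   "type": "integer"
  },
  "window_stride": {
   "default": 1,
   "minimum": 1,
   "title": "Window Stride",
   "type": "integer"
  },
  "training": {
   "$ref": "#/$defs/TrainingOverrides",
   "default": {
    "epochs": null,
    "batch_size": null,
    "learning_rate": null,
    "momentum": null,
    "weight_decay": null,
    "runs": null
   }
  },
  "protocol": {
   "$ref": "#/$defs/ProtocolOverrides",
   "default": {
    "n_subjects": null,
    "n_frames": null,
    "sigma": null
   }
  },
  "log_level": {
   "default": "INFO",
   "title": "Log Level",
   "type": "string"
  }
 },
 "title": "AppConfig",
 "type": "object"
}
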