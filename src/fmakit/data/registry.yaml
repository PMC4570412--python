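# Built-in registry of supported upper-limb test movements.
#
# Each entry names the movement, the sensors it requires, the ordered feature
# recipe evaluated on a recording, and (optionally) preprocessing overrides.
# Users may ship an edited copy and point the CLI at it via --registry.
version: 1
defaults:
  preprocess:
    target_frames: 45
    movement_threshold: 0.003
    filter_window: 5
    end_quiet_time: 0.5
    gyro_rest_threshold: 5.0
tests:
  - test_id: shoulder_abduction
    category: Shoulder
    movement: Abduction
    required_sensors: [skeleton]
    recipe:
      - {feature: joint_angle, joint: shoulder, frame: wrist_highest}
      - {feature: limb_orientation, limb: upper_arm, frame: wrist_highest}
      - {feature: limb_orientation, limb: forearm, frame: wrist_highest}
  - test_id: shoulder_external_rotation
    category: Shoulder
    movement: Ext. Rotation
    required_sensors: [skeleton]
    recipe:
      - {feature: joint_angle, joint: shoulder, frame: wrist_highest}
      - {feature: limb_orientation, limb: upper_arm, frame: wrist_highest}
      - {feature: limb_orientation, limb: forearm, frame: wrist_highest}
  - test_id: shoulder_abduction_0_90
    category: Shoulder
    movement: Abduction 0-90 deg
    required_sensors: [skeleton]
    recipe:
      - {feature: joint_angle, joint: shoulder, frame: wrist_highest}
      - {feature: limb_orientation, limb: upper_arm, frame: wrist_highest}
      - {feature: limb_orientation, limb: forearm, frame: wrist_highest}
  - test_id: shoulder_flexion_0_90
    category: Shoulder
    movement: Flexion 0-90 deg
    required_sensors: [skeleton]
    recipe:
      - {feature: joint_angle, joint: shoulder, frame: wrist_highest}
      - {feature: limb_orientation, limb: upper_arm, frame: wrist_highest}
      - {feature: limb_orientation, limb: forearm, frame: wrist_highest}
  - test_id: shoulder_flexion_90_180
    category: Shoulder
    movement: Flexion 90-180 deg
    required_sensors: [skeleton]
    recipe:
      - {feature: joint_angle, joint: shoulder, frame: wrist_highest}
      - {feature: limb_orientation, limb: upper_arm, frame: wrist_highest}
      - {feature: limb_orientation, limb: forearm, frame: wrist_highest}
  - test_id: elbow_flexion
    category: Elbow
    movement: Flexion
    required_sensors: [skeleton]
    recipe:
      - {feature: joint_angle, joint: elbow, frame: wrist_highest}
      - {feature: limb_orientation, limb: upper_arm, frame: wrist_highest}
      - {feature: limb_orientation, limb: forearm, frame: wrist_highest}
  - test_id: elbow_extension
    category: Elbow
    movement: Extension
    required_sensors: [skeleton]
    recipe:
      - {feature: joint_angle, joint: elbow, frame: wrist_lowest}
      - {feature: limb_orientation, limb: upper_arm, frame: wrist_lowest}
      - {feature: limb_orientation, limb: forearm, frame: wrist_lowest}
  - test_id: elbow_prosup_0
    category: Elbow
    movement: Pro/Supination at 0 deg
    required_sensors: [imu]
    recipe:
      - {feature: rotation_range}
      - {feature: smoothness}
      - {feature: movement_amount}
  - test_id: elbow_prosup_90
    category: Elbow
    movement: Pro/Supination at 90 deg
    required_sensors: [imu]
    recipe:
      - {feature: rotation_range}
      - {feature: smoothness}
      - {feature: movement_amount}
  - test_id: forearm_supination
    category: Forearm
    movement: Supination
    required_sensors: [imu]
    recipe:
      - {feature: rotation_range}
      - {feature: movement_amount}
  - test_id: forearm_pronation
    category: Forearm
    movement: Pronation
    required_sensors: [imu]
    recipe:
      - {feature: rotation_range}
      - {feature: movement_amount}
  - test_id: hand_mass_flexion
    category: Hand
    movement: Finger mass flexion
    required_sensors: [glove]
    recipe:
      - {feature: finger_state, mode: flexion}
  - test_id: hand_mass_extension
    category: Hand
    movement: Finger mass extension
    required_sensors: [glove]
    recipe:
      - {feature: finger_state, mode: extension}
  - test_id: hand_grasp_a
    category: Hand
    movement: Grasp a
    required_sensors: [glove, pressure]
    recipe:
      - {feature: finger_state, mode: flexion}
      - {feature: grip_strength}
  - test_id: hand_grasp_b
    category: Hand
    movement: Grasp b
    required_sensors: [glove, pressure]
    recipe:
      - {feature: finger_state, mode: flexion}
      - {feature: grip_strength}
  - test_id: hand_grasp_c
    category: Hand
    movement: Grasp c
    required_sensors: [glove, pressure]
    recipe:
      - {feature: finger_state, mode: flexion}
      - {feature: grip_strength}
  - test_id: hand_grasp_d
    category: Hand
    movement: Grasp d
    required_sensors: [glove, pressure]
    recipe:
      - {feature: finger_state, mode: flexion}
      - {feature: grip_strength}
  - test_id: hand_grasp_e
    category: Hand
    movement: Grasp e
    required_sensors: [glove, pressure]
    recipe:
      - {feature: finger_state, mode: flexion}
      - {feature: grip_strength}
  - test_id: wrist_flexext_elbow_90
    category: Wrist
    movement: Flex/Extension with elbow at 90 deg
    required_sensors: [imu]
    recipe:
      - {feature: rotation_range}
      - {feature: movement_amount}
  - test_id: wrist_flexext_elbow_0
    category: Wrist
    movement: Flex/Extension with elbow at 0 deg
    required_sensors: [imu]
    recipe:
      - {feature: rotation_range}
      - {feature: movement_amount}
  - test_id: wrist_circumduction
    category: Wrist
    movement: Circumduction
    required_sensors: [imu]
    recipe:
      - {feature: rotation_range}
      - {feature: smoothness}
      - {feature: movement_amount}
  - test_id: coord_tremor
    category: Coordination/Speed
    movement: Tremor
    required_sensors: [imu]
    recipe:
      - {feature: smoothness}
      - {feature: movement_amount}
  - test_id: coord_speed
    category: Coordination/Speed
    movement: Speed
    required_sensors: [imu]
    recipe:
      - {feature: movement_amount}
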