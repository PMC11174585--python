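# Kinect V2 25-joint skeleton layout.
# Coordinate convention: channel 0 = lateral x (left positive),
# channel 1 = vertical y (up), channel 2 = forward z (walking direction).
# Rest pose in metres for an average adult; joints are 0-indexed.
name: kinect25
n_joints: 25
joint_names:
  - spine_base      # 0
  - spine_mid       # 1
  - neck            # 2
  - head            # 3
  - shoulder_left   # 4
  - elbow_left      # 5
  - wrist_left      # 6
  - hand_left       # 7
  - shoulder_right  # 8
  - elbow_right     # 9
  - wrist_right     # 10
  - hand_right      # 11
  - hip_left        # 12
  - knee_left       # 13
  - ankle_left      # 14
  - foot_left       # 15
  - hip_right       # 16
  - knee_right      # 17
  - ankle_right     # 18
  - foot_right      # 19
  - spine_shoulder  # 20
  - hand_tip_left   # 21
  - thumb_left      # 22
  - hand_tip_right  # 23
  - thumb_right     # 24
edges:  # 24 bones
  - [0, 1]
  - [1, 20]
  - [20, 2]
  - [2, 3]
  - [20, 4]
  - [4, 5]
  - [5, 6]
  - [6, 7]
  - [7, 21]
  - [6, 22]
  - [20, 8]
  - [8, 9]
  - [9, 10]
  - [10, 11]
  - [11, 23]
  - [10, 24]
  - [0, 12]
  - [12, 13]
  - [13, 14]
  - [14, 15]
  - [0, 16]
  - [16, 17]
  - [17, 18]
  - [18, 19]
partitions:
  # spine_base (0) is shared between the two halves
  half:
    - [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 20, 21, 22, 23, 24]  # upper
    - [0, 12, 13, 14, 15, 16, 17, 18, 19]                          # lower
  limb:
    - [4, 5, 6, 7, 21, 22]      # left arm
    - [8, 9, 10, 11, 23, 24]    # right arm
    - [12, 13, 14, 15]          # left leg
    - [16, 17, 18, 19]          # right leg
    - [0, 1, 2, 3, 20]          # torso + head
mirror:  # left <-> right joint swaps (unlisted joints are on the midline)
  - [4, 8]
  - [5, 9]
  - [6, 10]
  - [7, 11]
  - [21, 23]
  - [22, 24]
  - [12, 16]
  - [13, 17]
  - [14, 18]
  - [15, 19]
lateral_channel: 0
center_joints: [0]
scale_joints: [0, 20]   # torso length = spine_base -> spine_shoulder
rest_pose:  # x, y, z per joint
  - [0.00, 1.00, 0.00]
  - [0.00, 1.25, 0.00]
  - [0.00, 1.50, 0.00]
  - [0.00, 1.65, 0.00]
  - [0.20, 1.45, 0.00]
  - [0.25, 1.20, 0.00]
  - [0.27, 0.98, 0.00]
  - [0.28, 0.90, 0.00]
  - [-0.20, 1.45, 0.00]
  - [-0.25, 1.20, 0.00]
  - [-0.27, 0.98, 0.00]
  - [-0.28, 0.90, 0.00]
  - [0.10, 0.95, 0.00]
  - [0.11, 0.50, 0.00]
  - [0.12, 0.10, 0.00]
  - [0.12, 0.02, 0.10]
  - [-0.10, 0.95, 0.00]
  - [-0.11, 0.50, 0.00]
  - [-0.12, 0.10, 0.00]
  - [-0.12, 0.02, 0.10]
  - [0.00, 1.42, 0.00]
  - [0.29, 0.84, 0.00]
  - [0.25, 0.88, 0.00]
  - [-0.29, 0.84, 0.00]
  - [-0.25, 0.88, 0.00]
# side: L / R / C (midline); group: arm / leg / torso / head
sides:  [C, C, C, C, L, L, L, L, R, R, R, R, L, L, L, L, R, R, R, R, C, L, L, R, R]
groups: [torso, torso, head, head, arm, arm, arm, arm, arm, arm, arm, arm,
         leg, leg, leg, leg, leg, leg, leg, leg, torso, arm, arm, arm, arm]
# fraction of the limb swing amplitude reaching each joint (distal > proximal)
swing_weight: [0.0, 0.0, 0.0, 0.0, 0.15, 0.5, 0.9, 1.0, 0.15, 0.5, 0.9, 1.0,
               0.2, 0.6, 1.0, 1.1, 0.2, 0.6, 1.0, 1.1, 0.0, 1.05, 0.95, 1.05, 0.95]
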