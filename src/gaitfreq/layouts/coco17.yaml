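# COCO 17-keypoint skeleton layout (2D/3D pose-estimator output).
# Same coordinate convention as kinect25: lateral x, vertical y, forward z.
name: coco17
n_joints: 17
joint_names:
  - nose            # 0
  - eye_left        # 1
  - eye_right       # 2
  - ear_left        # 3
  - ear_right       # 4
  - shoulder_left   # 5
  - shoulder_right  # 6
  - elbow_left      # 7
  - elbow_right     # 8
  - wrist_left      # 9
  - wrist_right     # 10
  - hip_left        # 11
  - hip_right       # 12
  - knee_left       # 13
  - knee_right      # 14
  - ankle_left      # 15
  - ankle_right     # 16
edges:
  - [0, 1]
  - [0, 2]
  - [1, 3]
  - [2, 4]
  - [0, 5]
  - [0, 6]
  - [5, 6]
  - [5, 7]
  - [7, 9]
  - [6, 8]
  - [8, 10]
  - [5, 11]
  - [6, 12]
  - [11, 12]
  - [11, 13]
  - [13, 15]
  - [12, 14]
  - [14, 16]
partitions:
  # the hip joints are shared between the two halves
  half:
    - [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12]  # upper
    - [11, 12, 13, 14, 15, 16]                    # lower
  limb:
    - [5, 7, 9]                  # left arm
    - [6, 8, 10]                 # right arm
    - [11, 13, 15]               # left leg
    - [12, 14, 16]               # right leg
    - [0, 1, 2, 3, 4, 5, 6, 11, 12]  # head + torso frame
mirror:
  - [1, 2]
  - [3, 4]
  - [5, 6]
  - [7, 8]
  - [9, 10]
  - [11, 12]
  - [13, 14]
  - [15, 16]
lateral_channel: 0
center_joints: [11, 12]   # mid-hip
scale_joints: [11, 5]     # torso length = left hip -> left shoulder
rest_pose:
  - [0.00, 1.60, 0.05]
  - [0.03, 1.63, 0.05]
  - [-0.03, 1.63, 0.05]
  - [0.07, 1.60, 0.00]
  - [-0.07, 1.60, 0.00]
  - [0.20, 1.45, 0.00]
  - [-0.20, 1.45, 0.00]
  - [0.25, 1.20, 0.00]
  - [-0.25, 1.20, 0.00]
  - [0.27, 0.95, 0.00]
  - [-0.27, 0.95, 0.00]
  - [0.10, 0.95, 0.00]
  - [-0.10, 0.95, 0.00]
  - [0.11, 0.50, 0.00]
  - [-0.11, 0.50, 0.00]
  - [0.12, 0.10, 0.00]
  - [-0.12, 0.10, 0.00]
sides:  [C, L, R, L, R, L, R, L, R, L, R, L, R, L, R, L, R]
groups: [head, head, head, head, head, arm, arm, arm, arm, arm, arm,
         leg, leg, leg, leg, leg, leg]
swing_weight: [0.0, 0.0, 0.0, 0.0, 0.0, 0.15, 0.15, 0.5, 0.5, 1.0, 1.0,
               0.2, 0.2, 0.6, 0.6, 1.0, 1.0]
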