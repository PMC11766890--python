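# Movement catalog: 16 range-of-motion tests across shoulder, hip and
# lumbar spine.  Planes, zero references, signs and caps are data, not code.
#
# Conventions (body frame: x = subject's left, y = up, z = subject's
# forward, toward the sensor):
#   * plane axes: sagittal = (y, z); frontal = (x, y); transverse = (x, z)
#   * sided entries are written for the RIGHT side; the left side is
#     obtained by substituting joint names and, for planes that contain
#     the x axis, flipping the sign and the zero reference's x component.
#   * sign multiplies the counter-clockwise angle from the projected zero
#     reference to the projected measurement vector so that the movement's
#     own direction reads positive.
#   * caps: shoulder forward flexion and abduction saturate at 180 deg,
#     the two external rotations at 90 deg; other movements are uncapped.
movements:
  - movement_id: shoulder-ff
    joint_group: shoulder
    sided: true
    proximal: shoulder-{side}
    distal: elbow-{side}
    plane: sagittal
    zero_reference: [0.0, -1.0, 0.0]
    sign: -1
    cap_degrees: 180.0
  - movement_id: shoulder-extension
    joint_group: shoulder
    sided: true
    proximal: shoulder-{side}
    distal: elbow-{side}
    plane: sagittal
    zero_reference: [0.0, -1.0, 0.0]
    sign: 1
    cap_degrees: null
  - movement_id: shoulder-abduction
    joint_group: shoulder
    sided: true
    proximal: shoulder-{side}
    distal: elbow-{side}
    plane: frontal
    zero_reference: [0.0, -1.0, 0.0]
    sign: -1
    cap_degrees: 180.0
  - movement_id: shoulder-adduction
    joint_group: shoulder
    sided: true
    proximal: shoulder-{side}
    distal: elbow-{side}
    plane: frontal
    zero_reference: [0.0, -1.0, 0.0]
    sign: 1
    cap_degrees: null
  - movement_id: shoulder-abd90-er
    joint_group: shoulder
    sided: true
    proximal: elbow-{side}
    distal: wrist-{side}
    plane: sagittal
    zero_reference: [0.0, 0.0, 1.0]
    sign: -1
    cap_degrees: 90.0
  - movement_id: shoulder-abd90-ir
    joint_group: shoulder
    sided: true
    proximal: elbow-{side}
    distal: wrist-{side}
    plane: sagittal
    zero_reference: [0.0, 0.0, 1.0]
    sign: 1
    cap_degrees: null
  - movement_id: shoulder-ff90-er
    joint_group: shoulder
    sided: true
    proximal: elbow-{side}
    distal: wrist-{side}
    plane: transverse
    zero_reference: [0.0, 0.0, 1.0]
    sign: 1
    cap_degrees: 90.0
  - movement_id: shoulder-ff90-ir
    joint_group: shoulder
    sided: true
    proximal: elbow-{side}
    distal: wrist-{side}
    plane: transverse
    zero_reference: [0.0, 0.0, 1.0]
    sign: -1
    cap_degrees: null
  - movement_id: hip-ff
    joint_group: hip
    sided: true
    proximal: hip-{side}
    distal: knee-{side}
    plane: sagittal
    zero_reference: [0.0, -1.0, 0.0]
    sign: -1
    cap_degrees: null
  - movement_id: hip-extension
    joint_group: hip
    sided: true
    proximal: hip-{side}
    distal: knee-{side}
    plane: sagittal
    zero_reference: [0.0, -1.0, 0.0]
    sign: 1
    cap_degrees: null
  - movement_id: hip-abduction
    joint_group: hip
    sided: true
    proximal: hip-{side}
    distal: knee-{side}
    plane: frontal
    zero_reference: [0.0, -1.0, 0.0]
    sign: -1
    cap_degrees: null
  - movement_id: hip-adduction
    joint_group: hip
    sided: true
    proximal: hip-{side}
    distal: knee-{side}
    plane: frontal
    zero_reference: [0.0, -1.0, 0.0]
    sign: 1
    cap_degrees: null
  - movement_id: spine-ff
    joint_group: spine
    sided: false
    proximal: spine-base
    distal: spine-mid
    plane: sagittal
    zero_reference: [0.0, 1.0, 0.0]
    sign: 1
    cap_degrees: null
  - movement_id: spine-extension
    joint_group: spine
    sided: false
    proximal: spine-base
    distal: spine-mid
    plane: sagittal
    zero_reference: [0.0, 1.0, 0.0]
    sign: -1
    cap_degrees: null
  - movement_id: spine-left-lateral
    joint_group: spine
    sided: false
    proximal: spine-base
    distal: spine-mid
    plane: frontal
    zero_reference: [0.0, 1.0, 0.0]
    sign: -1
    cap_degrees: null
  - movement_id: spine-right-lateral
    joint_group: spine
    sided: false
    proximal: spine-base
    distal: spine-mid
    plane: frontal
    zero_reference: [0.0, 1.0, 0.0]
    sign: 1
    cap_degrees: null
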